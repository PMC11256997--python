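#!/usr/bin/env python
"""Fit the buoyant-density-vs-fraction relationship for both treatments and
detect the light/heavy DNA windows from the 16S copy profiles.

Reads results/fixture/, writes results/windows.json.
"""

from pathlib import Path

from sipracs import fit_bd_vs_fraction, identify_windows
from sipracs import io as sio

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    runs = sio.read_fractions_csv(ROOT / "fixture" / "fractions.csv")
    for treatment, run in sorted(runs.items()):
        fit = fit_bd_vs_fraction(run)
        print(
            f"{treatment}: BD = {fit.intercept:.4f} {fit.slope:+.4f} x fraction "
            f"(r = {fit.r:.4f})"
        )
    windows = identify_windows(runs["12C"], runs["13C"])
    sio.write_windows_json(windows, ROOT / "windows.json")
    print(
        f"light window {windows.light_lo:.4f}-{windows.light_hi:.4f} g/ml, "
        f"heavy window {windows.heavy_lo:.4f}-{windows.heavy_hi:.4f} g/ml "
        f"(fallback: {windows.fallback})"
    )


if __name__ == "__main__":
    main()
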