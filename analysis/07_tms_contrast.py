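"""TMS real-vs-sham contrast on CancelTime and its timing dependence.

Simulates a sham-controlled pulse cohort (pulse 80 ms after the stop
signal), measures the percent change in CancelTime for real vs sham coil,
its correlation with the relative pulse time (pulse latency as % of sham
CancelTime), and the Failed-Stop latency proxy.  Also runs the delta=0
null cohort where the contrast should vanish.
"""

import sys
from pathlib import Path

import pandas as pd

from betastop.experiments import tms_experiment

OUT = Path("results/07_tms")


def main(seed: int = 1, n_subjects: int = 12) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    eff = tms_experiment(seed, n_subjects=n_subjects)
    pd.DataFrame([eff]).to_csv(OUT / "tms_contrast.tsv", sep="\t", index=False)
    print(f"real coil: CancelTime {eff['mean_cancel_real_ms']:.0f} ms vs sham "
          f"{eff['mean_cancel_sham_ms']:.0f} ms; mean change "
          f"{eff['mean_cancel_pct_change']:+.1f}% "
          f"(t = {eff['pct_change_t']:.2f}, p = {eff['pct_change_p']:.3g})")
    print("subjects pulsed closer to their cancellation show larger changes: "
          f"r = {eff['timing_r']:.2f} (p = {eff['timing_p']:.3g})")
    if "fs_proxy_real_ms" in eff:
        print(f"Failed-Stop latency proxy: real {eff['fs_proxy_real_ms']:.0f} "
              f"vs sham {eff['fs_proxy_sham_ms']:.0f} ms")

    null = tms_experiment(seed, n_subjects=n_subjects, delta_ms=0.0)
    pd.DataFrame([null]).to_csv(OUT / "tms_null.tsv", sep="\t", index=False)
    print(f"delta=0 null cohort: mean change "
          f"{null['mean_cancel_pct_change']:+.1f}% "
          f"(p = {null['pct_change_p']:.2f}) — no effect, as constructed")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1,
         int(sys.argv[2]) if len(sys.argv) > 2 else 12)
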