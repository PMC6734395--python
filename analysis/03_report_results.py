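"""Print a readable results report for a completed synthetic study.

Reads the outputs of 02_run_study.py and lays out the key statistics:
QC summary, paired condition comparisons (tCr- and water-referenced),
within-subject correlation structure with dependent-correlation z tests,
the condition × order ANOVA, dynamics clusters, and Vernier behaviour.
All numbers are synthetic-cohort outputs.
"""

import argparse
import json
from pathlib import Path

import pandas as pd


def _t(d: dict) -> str:
    return f"t_{d['df']} = {d['t']:.2f}, P = {d['p']:.3g}"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    args = ap.parse_args()
    stats = json.loads((args.study / "group_stats.json").read_text())
    qc = pd.read_csv(args.study / "qc.csv")

    print("== spectral quality (mean ± SD across acquisitions) ==")
    for col in ("fwhm_gaba_hz", "fwhm_glx_hz", "fwhm_tcr_hz",
                "freq_drift_sd_hz", "fit_error_gaba_pct", "fit_error_tcr_pct"):
        print(f"  {col}: {qc[col].mean():.2f} ± {qc[col].std():.2f}")

    for metab in ("gaba", "glx"):
        b = stats[metab]
        print(f"\n== {metab.upper()} ==")
        print(f"  single vs mixed: {_t(b['single_vs_mixed'])}")
        if "single_vs_mixed_water" in b:
            print(f"  (water-referenced): {_t(b['single_vs_mixed_water'])}")
        print(f"  rest vs single: {_t(b['rest_vs_single'])}")
        print(f"  rest vs mixed: {_t(b['rest_vs_mixed'])}")
        print(f"  rest1 vs rest2: {_t(b['rest1_vs_rest2'])}")
        c = b["corr_single_mixed_vs_rest_single"]
        print(
            f"  r(single, mixed) = {c['r_xy']:.2f} (P = {c['p_xy']:.3g}) vs "
            f"r(single, rest) = {c['r_xz']:.2f}: z = {c['z']:.2f}, P = {c['p_z']:.3g}"
        )
        a = b["anova_condition_order"]["textbook"]
        print(
            "  ANOVA condition F(1,{}) = {:.2f}, P = {:.3g}; order F = {:.2f} "
            "(P = {:.3g}); interaction F = {:.2f} (P = {:.3g})".format(
                a["condition"]["df"][1], a["condition"]["F"], a["condition"]["p"],
                a["order"]["F"], a["order"]["p"],
                a["interaction"]["F"], a["interaction"]["p"],
            )
        )

    dpath = args.study / "dynamics.json"
    if dpath.exists():
        dyn = json.loads(dpath.read_text())
        print("\n== dynamics (cluster-mass permutation) ==")
        for metab in ("gaba_tcr", "glx_tcr"):
            d = dyn[metab]
            print(
                f"  {metab}: {d['n_surviving']} surviving cluster(s), "
                f"threshold mass = {d['threshold']:.1f} ({d['n_perm']} permutations)"
            )
            for c in d["clusters"]:
                flag = "*" if c["survives"] else " "
                print(
                    f"   {flag} windows {c['start']}-{c['end']}: mass = "
                    f"{c['mass']:.1f}, corrected P = {c['p_corrected']:.3f}"
                )

    v = stats["vernier"]
    print("\n== Vernier task ==")
    print(f"  accuracy: {_t(v['accuracy'])}")
    print(f"  response time: {_t(v['response_time'])}")
    print(f"  bias single vs mixed: {_t(v['bias_single_vs_mixed'])}")


if __name__ == "__main__":
    main()
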