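"""Median-split Kaplan-Meier survival analysis per module.

Patients are scored by mean module expression, split at the median, and
the high and low groups compared with a log-rank test; the O/E hazard
ratio orients the effect (high vs low).  High enhancer activity is planted
to carry worse outcome (gamma = 0.5 per unit latent activity).
"""

import pandas as pd

from common import get_discovery, outdir
from sfcomod.io import write_result_table
from sfcomod.survival import logrank_km, median_split, module_score


def main() -> None:
    out = outdir("survival")
    cohort = get_discovery()
    modules = {
        "Enhancer": cohort.truth.module_genes("enhancer"),
        "Suppressor": cohort.truth.module_genes("suppressor"),
    }
    summary_rows, curve_rows = [], []
    for name, genes in modules.items():
        score = module_score(cohort.expression, genes)
        groups = median_split(score)
        km = logrank_km(cohort.survival, groups)
        summary_rows.append((name, km.chi_square, km.p_value, km.hazard_ratio,
                             km.observed["high"], km.expected["high"]))
        for grp, curve in km.curves.items():
            for _, r in curve.iterrows():
                curve_rows.append((name, grp, r["time"], r["survival"], r["at_risk"]))
        direction = "worse" if km.hazard_ratio > 1 else "better"
        print(f"{name:10s}: high-vs-low HR = {km.hazard_ratio:.2f} ({direction} outcome when high), "
              f"log-rank chi2 = {km.chi_square:.2f}, p = {km.p_value:.2e}")
    write_result_table(
        pd.DataFrame(summary_rows, columns=["module", "chi_square", "p_value",
                                            "hazard_ratio", "observed_high", "expected_high"]),
        str(out / "logrank.tsv"),
    )
    write_result_table(
        pd.DataFrame(curve_rows, columns=["module", "group", "time", "survival", "at_risk"]),
        str(out / "km_curves.tsv"),
    )
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
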