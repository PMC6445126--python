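"""Relate module expression to clinical covariates.

Per-gene median-normalized expression is averaged into per-patient module
scores and compared across tumor grade, mitotic score, ER status and
subtype with t-tests (2 groups) or one-way ANOVA (more).  Higher enhancer
activity should track higher grade/mitotic score and ER negativity.
"""

import pandas as pd

from common import get_discovery, outdir
from sfcomod.io import write_result_table
from sfcomod.survival import compare_groups, median_normalize, module_score


def main() -> None:
    out = outdir("clinical")
    cohort = get_discovery()
    norm = median_normalize(cohort.expression)
    modules = {
        "Enhancer": cohort.truth.module_genes("enhancer"),
        "Suppressor": cohort.truth.module_genes("suppressor"),
    }
    rows = []
    for name, genes in modules.items():
        score = module_score(norm, genes)
        for covariate in ("grade", "mitotic_score", "pleomorphism_score", "er_status", "subtype"):
            labels = cohort.clinical.data[covariate].dropna()
            res = compare_groups(score.loc[labels.index], labels)
            rows.append((name, covariate, res["test"], res["statistic"], res["p_value"]))
            print(f"{name:10s} vs {covariate:18s}: {res['test']:5s} "
                  f"statistic {res['statistic']:+8.3f}, p = {res['p_value']:.2e}")
    write_result_table(
        pd.DataFrame(rows, columns=["module", "covariate", "test", "statistic", "p_value"]),
        str(out / "clinical_tests.tsv"),
    )
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
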