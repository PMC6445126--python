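"""Generate the study's synthetic cohorts and write their tables.

Writes expression, matched normals, isoforms, clinical, survival, pair
design and ground truth for the discovery cohort, plus the validation
cohort's expression, under results/data/.
"""

import pandas as pd

from common import get_discovery, get_validation, outdir
from sfcomod.io import write_expression_table


def main() -> None:
    out = outdir("data")
    discovery = get_discovery()
    validation = get_validation(discovery)

    write_expression_table(discovery.expression, str(out / "expression_discovery.tsv"))
    write_expression_table(validation.expression, str(out / "expression_validation.tsv"))
    write_expression_table(discovery.normal_expression, str(out / "normals_discovery.tsv"))
    write_expression_table(discovery.isoforms, str(out / "isoforms_discovery.tsv"))
    discovery.pair_design.to_csv(out / "pairs.tsv", sep="\t", index=False)
    discovery.clinical.data.to_csv(out / "clinical.tsv", sep="\t", index_label="sample_id")
    discovery.survival.data.to_csv(out / "survival.tsv", sep="\t", index_label="sample_id")
    iso_map = pd.DataFrame(
        {
            "isoform_id": list(discovery.isoform_gene_map),
            "gene_id": list(discovery.isoform_gene_map.values()),
            "length": [discovery.isoform_lengths[i] for i in discovery.isoform_gene_map],
        }
    )
    iso_map.to_csv(out / "isoform_map.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(discovery.truth.to_json())

    n_genes, n_tumors = discovery.expression.shape
    print(f"discovery cohort: {n_genes} genes x {n_tumors} tumors, "
          f"{len(discovery.pair_design)} matched normal/tumor pairs")
    print(f"validation cohort: {validation.expression.shape[0]} genes "
          f"({len([g for g in validation.expression.gene_ids if g.startswith('SF')])} of 244 panel genes retained)")
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
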