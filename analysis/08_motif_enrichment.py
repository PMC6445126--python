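"""Promoter motif enrichment for the suppressor module.

Synthetic promoters (TSS-anchored) carry a CREB-like consensus planted
preferentially in suppressor-module genes; every promoter's -50..+450
window is scanned with the planted and a decoy PWM (best hit, both
strands) and the foreground's mean score is z-tested against the panel
background, Pscan-style.
"""

from common import STUDY_CONFIG, get_discovery, outdir
from sfcomod.io import write_promoters_fasta, write_result_table
from sfcomod.motifs import motif_enrichment_table
from sfcomod.synthetic import creb_like_pwm, decoy_pwm, generate_promoters


def main() -> None:
    out = outdir("motifs")
    cohort = get_discovery()
    fg = cohort.truth.module_genes("suppressor")
    bg = [g for g in cohort.truth.panel_genes if g not in set(fg)]
    promoters, plants = generate_promoters(STUDY_CONFIG, creb_like_pwm(), fg, bg)
    write_promoters_fasta(promoters, str(out / "promoters.fasta"))
    table = motif_enrichment_table(fg, promoters, [creb_like_pwm(), decoy_pwm()])
    write_result_table(table, str(out / "motif_enrichment.tsv"))
    for _, row in table.iterrows():
        print(f"{row['motif_id']}: z = {row['z']:+.2f}, one-tailed p = {row['p_value']:.2e} "
              f"(fg mean {row['fg_mean']:.3f} vs bg mean {row['bg_mean']:.3f}, "
              f"n_fg = {row['n_fg']}, n_bg = {row['n_bg']})")
    n_planted = sum(p is not None for g, p in plants.items() if g in set(fg))
    print(f"(truth: consensus planted in {n_planted}/{len(fg)} foreground promoters)")
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
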