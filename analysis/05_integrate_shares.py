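"""Per-gene share of the protein pool and heterozygous mutant dosage.

Multiplies each sample's PDUI-adjusted expression by the per-gene median
TE, closes to translated shares, and halves them for the mutant-dosage
estimate under equal allelic expression.
"""

import pandas as pd
from _common import RESULTS, load_or_simulate

from paralogshare import comp_stats, integration


def main() -> None:
    load_or_simulate()  # regenerates inputs if a previous step was skipped
    norm = pd.read_csv(RESULTS / "expression_normalized.tsv", sep="\t")
    te = pd.read_csv(RESULTS / "te.tsv", sep="\t", index_col=0)
    median_te = te.median(axis=1, skipna=True).to_dict()
    shares = integration.translated_share_table(norm, median_te)
    shares.to_csv(RESULTS / "translated_shares.tsv", sep="\t", index=False)
    summary = integration.summarize_shares(shares)
    summary.to_csv(RESULTS / "translated_summary.tsv", sep="\t", index=False)
    print(summary.round(2).to_string(index=False))

    wide = shares.pivot(index="sample_id", columns="gene_id",
                        values="translated_fraction")
    hot = comp_stats.hotelling_one_sample(
        comp_stats.ilr_matrix(wide.to_numpy()))
    print(f"translated composition vs uniform: Hotelling T2 = "
          f"{hot.statistic:.1f}, p = {hot.p:.3g}")


if __name__ == "__main__":
    main()
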