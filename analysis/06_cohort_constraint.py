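"""Variant-consequence statistics: registry events and constraint ratios.

The published registry any-cardiac-event table (shipped as a fixture) is
tested with chi-squared; gnomAD-scale constraint counts are simulated at
the published o/e ratios and summarized with 90% normalized-likelihood
confidence intervals.
"""

import pandas as pd
from _common import GENES, RESULTS, ROOT, SEED

from paralogshare import cohort_constraint, io_formats
from paralogshare.synthetic_data import simulate_constraint


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table = io_formats.read_cohort_table(ROOT / "fixtures" / "registry_any_event.tsv")
    chi = cohort_constraint.chi_squared_test(table)
    pct = cohort_constraint.event_percentages(table)
    pct.to_csv(RESULTS / "registry_event_percentages.tsv", sep="\t", index=False)
    print(pct.to_string(index=False))
    print(f"chi-squared: statistic = {chi.statistic:.3f}, df = {chi.df}, "
          f"p = {chi.p:.4f} ({'significant' if chi.significant else 'ns'})")

    # constraint: expected counts at gnomAD scale, observed simulated at the
    # published o/e ratios (the real observed/expected counts are not public
    # in tabular form at gene level here)
    mis = simulate_constraint([127.0, 150.0, 200.0], [0.11, 0.20, 0.29],
                              SEED, genes=GENES, variant_class="missense")
    plof = simulate_constraint([10.7, 11.5, 11.0], [0.0, 0.0, 0.27],
                               SEED + 1, genes=GENES, variant_class="plof")
    oe = cohort_constraint.oe_table(mis + plof, ci_level=0.90)
    oe.to_csv(RESULTS / "constraint_oe.tsv", sep="\t", index=False)
    print(oe.to_string(index=False))


if __name__ == "__main__":
    main()
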