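"""Generate the synthetic left-ventricle study dataset.

Eighty samples of the three calmodulin genes at the published study
conditions: 3'-UTR lengths 3544/694/1640 nt, identical 450-nt CDS, PDUI
means 0.39/0.81/0.64, mean expression shares 36.8/41.9/21.3% and TEs
3.01/2.59/1.26.  Raw files (bedGraph coverage, count matrices) go to
scratch/sim; the generating truth tables to results/.
"""

from _common import RESULTS, SCRATCH, load_or_simulate

from paralogshare.synthetic_data import write_dataset


def main() -> None:
    ds = load_or_simulate()
    write_dataset(ds, SCRATCH)
    ds.truth.composition.to_csv(RESULTS / "truth_composition.tsv", sep="\t",
                                index_label="sample_id")
    ds.truth.te.to_frame().to_csv(RESULTS / "truth_te.tsv", sep="\t",
                                  index_label="gene_id")
    print(f"wrote raw dataset ({ds.rna.counts.shape[1]} samples, "
          f"{len(ds.coverage)} coverage tracks) to {SCRATCH}")
    print("truth tables in results/: mean shares",
          ds.truth.composition.mean().round(3).to_dict())


if __name__ == "__main__":
    main()
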