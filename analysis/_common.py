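"""Shared plumbing for the numbered analysis drivers.

The study dataset is regenerated deterministically (seed 1) by each
driver; 01_simulate.py additionally writes the raw files (coverage
bedGraphs, count matrices) under scratch/sim.  The small result tables
land in results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"
SEED = 1
GENES = ("CALM1", "CALM2", "CALM3")


def load_or_simulate():
    """The study dataset (80 left-ventricle-like samples, seed 1)."""
    from paralogshare.synthetic_data import SimulationConfig, simulate_dataset

    RESULTS.mkdir(exist_ok=True)
    return simulate_dataset(SimulationConfig(n_samples=80, seed=SEED))
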