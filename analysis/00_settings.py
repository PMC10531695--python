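"""Shared settings for the analysis scripts.

The study population is simulated at the shape of the motivating dataset:
221 wheat genotypes on a dense biallelic SNP panel (2,000 markers here, a
desk-scale stand-in for a post-QC chip panel), three subpopulation clusters,
and the NUE trait scored under low-N and high-N environments.
"""

from pathlib import Path

from gsnue.simulate import PopulationConfig

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results" / "analysis"
POPULATION = PopulationConfig(n_genotypes=221, n_markers=2000, seed=SEED)
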