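"""Parametrize leucine end to end and print its rotamer wells.

Builds the capped dipeptide from SMILES, generates a seeded conformer
ensemble, fits the chi-angle mixture and writes rotlib + PDB rotamer
files into ./example_out.
"""

from rotafit.pipeline import RunConfig, run_pipeline

config = RunConfig(
    input_text="NC(CC(C)C)C(=O)O",  # leucine free amino acid
    input_format="smiles",
    name="LEU",
    n_generate=2000,   # fitted ensemble; 10_000 is the production default
    n_keep=100,        # explicit PDB rotamers kept after UFF ranking
    seed=1,
    mode="both",
    output_dir="example_out",
)

summary = run_pipeline(config)

print(f"chi angles: {summary['n_chi']}")
print(f"per-chi bin counts: {summary['per_chi_bin_counts']}")
print(f"rotamer wells: {summary['n_wells']}")
for w in summary["wells"]:
    print(f"  bins {w['bin']}  chi {w['chi_means']}  "
          f"std {w['chi_stds']}  p={w['density']:.3f}")
print(f"outputs: {summary['outputs']}")
# Each well is one recurring side-chain conformation: its per-chi mean
# angles, spread (for off-rotamer scoring), and probability in the
# ensemble. Leucine's 3 x 3 staggered bins yield the classic nine wells.
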