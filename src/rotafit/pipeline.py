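"""End-to-end parametrization pipeline and library comparison.

One call takes a residue description to a rotamer library:

    load -> cap into dipeptide -> derive chis -> embed conformers
         -> UFF-score (capless) -> rank/filter -> extract frame samples
         -> mixture fit -> prune -> per-chi bins -> assign/merge
         -> truncate to four chis -> write rotlib + PDB rotamers

Residues the rotlib format cannot represent — no chi angles, a multiply
substituted alpha carbon, or a side chain conjugated back onto the
backbone — fall back to PDB-rotamer output only.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import conformers, residue_model, rotlib_io, well_fitting
from .dihedral_geometry import extract_chi_samples
from .errors import RotafitError
from .rotlib_io import RotamerLibrary, match_wells
from .well_fitting import FitConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one parametrization run needs.

    ``n_generate`` poses are embedded; the energy-ranked best ``n_keep``
    become the PDB-rotamer ensemble.  The mixture is fitted on the full
    generated ensemble by default (``fit_filtered_only=False``) so that
    rare wells stay represented; set the flag to fit only the kept subset.
    A single ``seed`` drives embedding and fitting through fixed offsets.
    """

    input_path: str | None = None
    input_text: str | None = None
    input_format: str = "sdf"
    backbone: dict[str, int] | None = None
    name: str = "UNK"
    n_generate: int = 10_000
    n_keep: int = 100
    fit_filtered_only: bool = False
    seed: int = 1
    density_threshold: float = 0.005
    use_experimental_torsions: bool = True
    output_dir: str = "."
    mode: str = "both"  # rotlib | pdb_rotamers | both
    fit: FitConfig = field(default_factory=FitConfig)

    def __post_init__(self):
        if not 0.0 < self.density_threshold < 1.0:
            raise ValueError("density threshold must lie in (0, 1)")
        if self.n_generate < 1 or self.n_keep < 1:
            raise ValueError("conformer counts must be positive")
        if self.mode not in ("rotlib", "pdb_rotamers", "both"):
            raise ValueError(f"unknown output mode {self.mode!r}")
        self.fit.seed = self.seed + 7919  # fitting sub-seed, offset from embedding
        self.fit.density_threshold = self.density_threshold


def _load_spec(config: RunConfig) -> residue_model.SideChainSpec:
    if config.input_text is not None:
        text = config.input_text
    elif config.input_path is not None:
        text = Path(config.input_path).read_text()
    else:
        raise ValueError("RunConfig needs input_text or input_path")
    return residue_model.load_residue(text, config.input_format,
                                      config.backbone, name=config.name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full parametrization and return a summary record.

    The summary (well count, per-chi bin counts, output paths, elapsed
    time) is also serialized as JSON next to the outputs.
    """
    t_start = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    spec = _load_spec(config)
    dipeptide = residue_model.build_dipeptide(spec)
    chi_defs = residue_model.derive_chi_definitions(dipeptide)
    logger.info("stage=residue name=%s n_chi=%d", config.name, len(chi_defs))

    rotlib_capable = (bool(chi_defs)
                      and dipeptide.is_monosubstituted
                      and not dipeptide.is_backbone_conjugated)
    if not rotlib_capable:
        reason = ("backbone-conjugated side chain" if dipeptide.is_backbone_conjugated
                  else "no rotatable chi angles" if not chi_defs
                  else "alpha carbon is not monosubstituted")
        logger.warning("stage=routing rotlib output disabled: %s; "
                       "falling back to PDB rotamers only", reason)

    ensemble = conformers.generate_conformers(
        dipeptide, config.n_generate, config.seed,
        use_experimental_torsions=config.use_experimental_torsions)
    # energy ranking feeds the PDB-rotamer output and (optionally) the fit
    # subset; a rotlib-only unfiltered run never needs the scores
    need_scores = (config.mode in ("pdb_rotamers", "both")
                   or config.fit_filtered_only
                   or not rotlib_capable)
    if need_scores:
        ensemble = conformers.score_sidechain_energy(ensemble)
        kept = conformers.rank_and_filter(ensemble, config.n_keep)
    else:
        kept = ensemble
    logger.info("stage=conformers generated=%d kept=%d", len(ensemble), len(kept))

    summary: dict = {
        "name": config.name,
        "n_chi": len(chi_defs),
        "n_generated": len(ensemble),
        "n_kept": len(kept),
        "seed": config.seed,
        "rotlib_capable": rotlib_capable,
        "outputs": {},
    }

    if config.mode in ("pdb_rotamers", "both") or not rotlib_capable:
        pdb_path = outdir / f"{config.name}_rotamers.pdb"
        # rigid side chains (alanine-like: no chi, no ring through the
        # backbone) collapse to the single best pose
        rigid = not chi_defs and not dipeptide.is_backbone_conjugated
        pdb_source = conformers.rank_and_filter(ensemble, 1) if rigid else kept
        rotlib_io.write_pdb_rotamers(pdb_source, strip_caps_flag=False, out=pdb_path)
        summary["outputs"]["pdb_rotamers"] = str(pdb_path)
        logger.info("stage=output wrote %s (%d models)", pdb_path, len(pdb_source))

    if rotlib_capable and config.mode in ("rotlib", "both"):
        fit_ensemble = kept if config.fit_filtered_only else ensemble
        samples = extract_chi_samples(fit_ensemble, chi_defs)
        wells, bins = well_fitting.fit_wells(samples, config.fit)
        wells, out_chi_defs = rotlib_io.truncate_to_four_chi(wells, chi_defs)
        lib = RotamerLibrary(residue_code=config.name, wells=wells,
                             n_chi=len(out_chi_defs),
                             n_samples=samples.n_conformers,
                             seed=config.seed)
        rotlib_path = outdir / f"{config.name}.rotlib"
        rotlib_io.write_rotlib(lib, rotlib_path)
        summary["outputs"]["rotlib"] = str(rotlib_path)
        summary["n_wells"] = len(lib.wells)
        summary["per_chi_bin_counts"] = [len(b) for b in bins]
        summary["wells"] = [
            {"bin": list(w.bin_assignment),
             "chi_means": [round(x, 2) for x in w.chi_means],
             "chi_stds": [round(x, 2) for x in w.chi_stds],
             "density": round(w.density, 6)}
            for w in lib.wells]
        logger.info("stage=output wrote %s (%d wells, bins %s)",
                    rotlib_path, len(lib.wells), summary["per_chi_bin_counts"])

    summary["elapsed_s"] = round(time.time() - t_start, 2)
    with open(outdir / f"{config.name}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def compare_distributions(lib_a: RotamerLibrary,
                          lib_b: RotamerLibrary) -> dict:
    """Greedy well matching between two libraries of equal chi count.

    Returns the total variation distance between the matched density
    vectors (unmatched wells contribute their full density) plus a
    per-matched-well table of mean/std deltas.
    """
    if lib_a.n_chi != lib_b.n_chi:
        raise RotafitError(
            f"chi-count mismatch: {lib_a.n_chi} vs {lib_b.n_chi}")
    pairs = match_wells(lib_a.wells, lib_b.wells)
    table = []
    matched_a = set()
    matched_b = set()
    for i, j, dist in pairs:
        wa, wb = lib_a.wells[i], lib_b.wells[j]
        matched_a.add(i)
        matched_b.add(j)
        table.append({
            "a_means": list(wa.chi_means), "b_means": list(wb.chi_means),
            "mean_delta": dist,
            "std_delta": [abs(x - y) for x, y in zip(wa.chi_stds, wb.chi_stds)],
            "density_a": wa.density, "density_b": wb.density,
        })
    tvd = 0.5 * sum(abs(r["density_a"] - r["density_b"]) for r in table)
    tvd += 0.5 * sum(w.density for i, w in enumerate(lib_a.wells) if i not in matched_a)
    tvd += 0.5 * sum(w.density for j, w in enumerate(lib_b.wells) if j not in matched_b)
    return {"total_variation": tvd,
            "n_matched": len(table),
            "matched_wells": table}


def config_from_yaml(source) -> RunConfig:
    """Build a RunConfig from a YAML mapping mirroring the CLI flags."""
    import yaml
    if hasattr(source, "read"):
        data = yaml.safe_load(source)
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    fit_kwargs = data.pop("fit", {}) or {}
    return RunConfig(fit=FitConfig(**fit_kwargs), **data)
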