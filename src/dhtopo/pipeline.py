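"""Orchestration: structure -> bonds -> curvature -> hydration reports.

Runs the full analysis for one protein (or a batch), producing the
per-bond table, pooled ¼ Å θ spectra per bond class, the d_min
distribution per class, and the θ-binned hydration profile, with explicit
TSV/JSON interchange so each stage is independently re-runnable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bhb_wrapping import (
    DEFAULT_DESOLVATION_RADIUS,
    DEFAULT_EBHB_THRESHOLD,
    annotate_bonds,
    bonds_table,
)
from .data import PROBE_RADIUS
from .hydration_analysis import (
    HydrationRecord,
    action,
    bhb_hydration,
    theta_profiles,
    water_hb_graph,
)
from .structure_model import (
    ProteinStructure,
    SolventFrame,
    classify_nonpolar_groups,
    place_amide_hydrogens,
    read_solvent_frames,
    read_structure,
)
from .surface_topography import (
    DEFAULT_PATCH_RADIUS,
    DEFAULT_POINT_SPACING,
    DEFAULT_VICINITY_RADIUS,
    CurvatureSpectrum,
    bhb_vicinity_spectrum,
    build_envelope,
    estimate_theta,
    protein_theta_spectrum,
    theta_histogram,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ProteinReport", "run_protein", "run_batch"]

D_MIN_BIN = 0.25  # Å, distance-distribution coarse graining


@dataclass
class RunConfig:
    """All knobs of one analysis run, each at its standard default."""

    pdb_path: str | None = None
    frames_path: str | None = None
    out_dir: str | None = None
    model_index: int = 0
    no_cutoff: float = 3.2  # Å, donor N to acceptor O
    angle_min: float = 120.0  # degrees
    angle_max: float = 180.0
    min_seq_separation: int = 2
    desolvation_radius: float = DEFAULT_DESOLVATION_RADIUS  # 6 Å
    ebhb_threshold: int = DEFAULT_EBHB_THRESHOLD  # 19 wrappers
    threshold_from_population: bool = False  # recompute floor(mean - SD)
    probe_radius: float = PROBE_RADIUS  # 1.4 Å
    point_spacing: float = DEFAULT_POINT_SPACING  # 0.5 Å
    patch_radius: float = DEFAULT_PATCH_RADIUS  # 2.5 Å
    vicinity_radius: float = DEFAULT_VICINITY_RADIUS  # 3 Å
    theta_bin: float = 0.25  # Å
    theta_max: float = 10.0  # Å, sub-nanoscale bound
    flatness_cutoff: float = 20.0  # Å
    oo_cutoff: float = 3.2  # Å, water-water
    field_radius: float = 2.5  # Å, g(r) ball
    distance_only_hb: bool = False
    include_interchain: bool = False
    seed: int = 0

    def hash(self) -> str:
        fields = asdict(self)
        fields.pop("out_dir", None)  # where the report lands is not analysis config
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ProteinReport:
    """All reportable outputs of one protein run."""

    name: str
    config: RunConfig
    bonds: pd.DataFrame
    spectra: list[CurvatureSpectrum]
    bhb_spectrum: CurvatureSpectrum
    ebhb_spectrum: CurvatureSpectrum
    hydration: list[HydrationRecord] = field(default_factory=list)
    theta_profile: pd.DataFrame | None = None
    actions: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def d_min_distribution(self, bin_width: float = D_MIN_BIN) -> pd.DataFrame:
        """Counts and densities of d_min per bond class (EBHB vs wrapped)."""
        rows = []
        for rec in self.hydration:
            rows.append(
                {
                    "d_min": rec.d_min,
                    "klass": "EBHB" if rec.bond.is_ebhb else "wrapped",
                }
            )
        if not rows:
            return pd.DataFrame(columns=["klass", "bin_left", "count", "density"])
        df = pd.DataFrame(rows)
        df["bin_left"] = np.floor(df["d_min"] / bin_width) * bin_width
        out = (
            df.groupby(["klass", "bin_left"]).size().rename("count").reset_index()
        )
        out["density"] = out.groupby("klass")["count"].transform(
            lambda c: c / c.sum()
        )
        return out

    def theta_spectrum_table(self) -> pd.DataFrame:
        edges, bhb_counts = self.bhb_spectrum.histogram()
        _, ebhb_counts = self.ebhb_spectrum.histogram()
        well = bhb_counts - ebhb_counts
        return pd.DataFrame(
            {
                "bin_left": edges[:-1],
                "bhb_count": bhb_counts,
                "ebhb_count": ebhb_counts,
                "well_wrapped_count": well,
                "bhb_density": _safe_density(bhb_counts),
                "ebhb_density": _safe_density(ebhb_counts),
            }
        )

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.bonds.to_csv(out / "bonds.tsv", sep="\t", index=False)
        self.theta_spectrum_table().to_csv(
            out / "theta_spectrum.tsv", sep="\t", index=False
        )
        per_bond = {
            s.label: {
                "summary_theta": s.summary_theta,
                "buried": bool(s.buried),
                "n_points": int(s.thetas.size),
                "thetas": [round(float(t), 4) for t in s.thetas],
            }
            for s in self.spectra
        }
        (out / "spectra.json").write_text(json.dumps(per_bond, indent=1))
        if self.hydration:
            pd.DataFrame(
                [
                    {
                        "bond": r.bond.label,
                        "d_min": round(r.d_min, 4),
                        "g_min": round(r.g_min, 4),
                        "n_frames": r.n_frames,
                        "is_ebhb": r.bond.is_ebhb,
                        "summary_theta": r.bond.summary_theta,
                    }
                    for r in self.hydration
                ]
            ).to_csv(out / "hydration.tsv", sep="\t", index=False)
            self.d_min_distribution().to_csv(
                out / "d_min_distribution.tsv", sep="\t", index=False
            )
        if self.theta_profile is not None and len(self.theta_profile):
            self.theta_profile.to_csv(out / "theta_profile.tsv", sep="\t", index=False)
        if self.actions is not None:
            self.actions.to_csv(out / "action.tsv", sep="\t", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=1))


def _safe_density(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def run_protein(
    config: RunConfig,
    structure: ProteinStructure | None = None,
    frames: list[SolventFrame] | None = None,
    name: str = "protein",
) -> ProteinReport:
    """Execute the full pipeline for one protein.

    Inputs may be given as paths in ``config`` or as in-memory objects.
    Solvent frames are optional; without them the hydration tables stay
    empty.  The run is deterministic for fixed inputs and configuration.
    """
    if structure is None:
        if config.pdb_path is None:
            raise ValueError("no structure given (config.pdb_path or structure=)")
        structure = read_structure(config.pdb_path, config.model_index)
        name = Path(config.pdb_path).stem
    if frames is None and config.frames_path:
        frames = read_solvent_frames(config.frames_path)
    if frames is None and structure.solvent is not None:
        frames = [structure.solvent]

    if not structure.hydrogens_placed:
        place_amide_hydrogens(structure)
    if not structure.nonpolar_classified:
        classify_nonpolar_groups(structure)

    bonds = annotate_bonds(
        structure,
        desolvation_radius=config.desolvation_radius,
        threshold=None if config.threshold_from_population else config.ebhb_threshold,
        no_cutoff=config.no_cutoff,
        angle_range=(config.angle_min, config.angle_max),
        min_seq_separation=config.min_seq_separation,
        include_interchain=config.include_interchain,
    )
    logger.info("%s: %d BHBs, %d EBHBs", name, len(bonds), sum(b.is_ebhb for b in bonds))

    envelope = build_envelope(structure, config.probe_radius, config.point_spacing)
    estimate_theta(envelope, config.patch_radius, flatness_cutoff=config.flatness_cutoff)
    spectra = [
        bhb_vicinity_spectrum(b, envelope, config.vicinity_radius) for b in bonds
    ]
    bhb_spec, ebhb_spec = protein_theta_spectrum(spectra)

    hydration: list[HydrationRecord] = []
    actions_df = None
    profile = None
    if frames:
        graphs = [
            water_hb_graph(
                fr, oo_cutoff=config.oo_cutoff, distance_only=config.distance_only_hb
            )
            for fr in frames
        ]
        hydration = [bhb_hydration(b, frames, graphs) for b in bonds]
        profile = theta_profiles(hydration, config.theta_bin)
        actions_df = pd.DataFrame(
            [
                {"frame": a.frame_index, "A": a.A}
                for a in (action(g) for g in graphs)
            ]
        )

    report = ProteinReport(
        name=name,
        config=config,
        bonds=bonds_table(bonds),
        spectra=spectra,
        bhb_spectrum=bhb_spec,
        ebhb_spectrum=ebhb_spec,
        hydration=hydration,
        theta_profile=profile,
        actions=actions_df,
        provenance={
            "name": name,
            "config_hash": config.hash(),
            "version": __version__,
            "n_residues": structure.n_residues,
            "n_bonds": len(bonds),
            "n_frames": len(frames) if frames else 0,
        },
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report


def run_batch(
    runs: list[tuple[RunConfig, ProteinStructure | None, list[SolventFrame] | None, str]],
    out_dir: str | Path | None = None,
) -> dict:
    """Run several proteins and pool class-wise distributions.

    Each item is (config, structure or None, frames or None, name).
    Per-protein failures are logged and skipped; the batch fails only if
    every run fails.  Pooled histograms are sums of the per-protein
    histograms.
    """
    reports: list[ProteinReport] = []
    failures: list[str] = []
    for config, structure, frames, name in runs:
        try:
            reports.append(run_protein(config, structure, frames, name))
        except Exception as exc:
            logger.error("run %s failed: %s", name, exc)
            failures.append(name)
    if not reports:
        raise RuntimeError(f"all {len(failures)} batch inputs failed")

    pooled_bhb = np.concatenate([r.bhb_spectrum.thetas for r in reports])
    pooled_ebhb = np.concatenate([r.ebhb_spectrum.thetas for r in reports])
    edges, bhb_counts = theta_histogram(pooled_bhb)
    _, ebhb_counts = theta_histogram(pooled_ebhb)
    hydration_rows = [
        {
            "protein": r.name,
            "bond": rec.bond.label,
            "d_min": rec.d_min,
            "g_min": rec.g_min,
            "is_ebhb": rec.bond.is_ebhb,
            "summary_theta": rec.bond.summary_theta,
        }
        for r in reports
        for rec in r.hydration
    ]
    pooled = {
        "reports": reports,
        "failures": failures,
        "theta_edges": edges,
        "bhb_counts": bhb_counts,
        "ebhb_counts": ebhb_counts,
        "hydration": pd.DataFrame(hydration_rows),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "bin_left": edges[:-1],
                "bhb_count": bhb_counts,
                "ebhb_count": ebhb_counts,
                "bhb_density": _safe_density(bhb_counts),
                "ebhb_density": _safe_density(ebhb_counts),
            }
        ).to_csv(out / "pooled_theta_spectrum.tsv", sep="\t", index=False)
        pooled["hydration"].to_csv(out / "pooled_hydration.tsv", sep="\t", index=False)
    return pooled
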