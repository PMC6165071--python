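"""End-to-end multi-system comparison pipeline.

Orchestrates generate-or-load -> stability observables -> catalytic
geometry -> interaction network -> PCA/FEL -> machine-readable report,
for any number of systems, with full determinism: a config plus seed
reproduces byte-identical CSV outputs (floats are written at 6
significant digits, and every output file is checksummed into the run
manifest).

The built-in synthetic demo models a four-system comparison of an
alpha/beta-hydrolase (wild type and a cap-domain point mutant, each bound
to one of two substrate epimers): a 264-residue helical backbone whose
cap segment (residues 161-190) undergoes a hard helix-to-turn switch
with a per-system turn fraction, planted cap-to-C-terminal hydrogen-bond
occupancies, planted catalytic-triad distances and nucleophilic-attack
angles, and correlated residue noise linking the cap to the 241-245
region.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry as geom
from . import network as netmod
from . import observables as obs
from . import pca as pcamod
from . import synthetic as syn
from .structure import (
    Ensemble,
    read_multimodel_pdb,
    select_atoms,
    subset_atoms,
    write_multimodel_pdb,
)

__all__ = [
    "PipelineConfig",
    "SystemSpec",
    "PipelineError",
    "load_config",
    "run_pipeline",
    "compare_systems",
    "default_demo_systems",
]

log = logging.getLogger("rinpipe")

FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SystemSpec:
    """One system of the comparison.

    ``path`` is set in PDB mode; the remaining fields parameterise the
    synthetic generator (occupancies as fractions, distances in A,
    angles in degrees).
    """

    name: str
    path: str | None = None
    turn_fraction: float = 0.0
    triad_distance_mean: float = 7.0
    oae_distance_mean: float = 6.5
    attack_angle_mean: float = 75.0
    hbond_occupancies: list = field(default_factory=list)
    # list of [donor_resid, donor_name, acceptor_resid, acceptor_name, frac]


# per-system study conditions of the built-in four-system demo
_DEMO = [
    # name, turn %, triad dist, substrate-O dist, attack angle
    ("WT_aZOL", 0.034, 7.0, 6.5, 75.0),
    ("V153H_aZOL", 0.628, 3.7, 6.5, 110.0),
    ("WT_bZOL", 0.046, 7.0, 4.0, 75.0),
    ("V153H_bZOL", 0.841, 7.0, 4.0, 75.0),
]

# cap-to-241/245 hydrogen-bond occupancies (%) per demo system
_DEMO_HBONDS = [
    ((162, "OG"), (240, "O"), [11.39, 41.96, 0.0, 24.48]),
    ((162, "OG"), (242, "N"), [23.49, 42.59, 15.67, 36.86]),
    ((162, "N"), (241, "O"), [16.38, 33.52, 22.52, 36.61]),
    ((162, "OG"), (243, "N"), [24.26, 48.35, 10.25, 34.03]),
]

_DEMO_RESNAMES = {
    32: "GLY", 102: "SER", 126: "GLU", 153: "VAL", 154: "MET",
    158: "VAL", 161: "GLY", 162: "SER", 163: "GLU", 165: "TRP",
    183: "TRP", 240: "GLY", 241: "MET", 242: "HIS", 243: "PHE",
    245: "TYR",
}


def default_demo_systems() -> list[SystemSpec]:
    systems = []
    for k, (name, turn, triad, oae, angle) in enumerate(_DEMO):
        hbonds = [
            [d[0], d[1], a[0], a[1], occ[k] / 100.0]
            for d, a, occ in _DEMO_HBONDS
        ]
        systems.append(
            SystemSpec(
                name=name,
                turn_fraction=turn,
                triad_distance_mean=triad,
                oae_distance_mean=oae,
                attack_angle_mean=angle,
                hbond_occupancies=hbonds,
            )
        )
    return systems


@dataclass
class PipelineConfig:
    """All thresholds and selections of the pipeline, with defaults."""

    mode: str = "synthetic"  # "synthetic" | "pdb"
    systems: list[SystemSpec] = field(default_factory=default_demo_systems)
    output_dir: str = "rinpipe_out"
    seed: int = 1
    n_frames: int = 150
    n_residues: int = 264
    # network
    i_min: float = 2.5
    contact_cutoff: float = 4.5
    c_floor: float = 0.5
    hub_min: int = 4
    # geometry
    hbond_distance: float = 3.5
    hbond_angle: float = 30.0
    attack_center: float = 110.0
    attack_halfwidth: float = 20.0
    cap_segment: tuple[int, int] = (161, 190)
    turn_range: tuple[int, int] = (161, 175)
    # observables
    burn_in: float = 0.05
    sasa_points: int = 960
    # pca / fel
    fel_bins: int = 50
    histogram_bins: int = 20
    temperature: float | None = None
    # synthetic noise scale (A)
    noise_sigma: float = 0.05

    def validate(self) -> None:
        checks = [
            ("i_min", 0.0 < self.i_min <= 100.0, "(0, 100]"),
            ("contact_cutoff", self.contact_cutoff > 0, "> 0"),
            ("c_floor", 0.0 <= self.c_floor <= 1.0, "[0, 1]"),
            ("hub_min", self.hub_min >= 1, ">= 1"),
            ("hbond_distance", self.hbond_distance > 0, "> 0"),
            ("hbond_angle", 0 < self.hbond_angle <= 180, "(0, 180]"),
            ("attack_halfwidth", self.attack_halfwidth > 0, "> 0"),
            ("burn_in", 0.0 <= self.burn_in < 1.0, "[0, 1)"),
            ("sasa_points", self.sasa_points >= 100, ">= 100"),
            ("fel_bins", self.fel_bins >= 2, ">= 2"),
            ("histogram_bins", self.histogram_bins >= 1, ">= 1"),
            ("n_frames", self.n_frames >= 4, ">= 4"),
            ("n_residues", self.n_residues >= 20, ">= 20"),
            ("mode", self.mode in ("synthetic", "pdb"), "synthetic|pdb"),
        ]
        for key, ok, valid in checks:
            if not ok:
                raise ValueError(
                    f"config key {key!r} = {getattr(self, key)!r} outside "
                    f"valid range {valid}"
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cap_segment"] = list(self.cap_segment)
        d["turn_range"] = list(self.turn_range)
        return d


def load_config(path: str | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config, fill defaults, reject unknown keys."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "systems" in data and data["systems"] is not None:
        data["systems"] = [
            s if isinstance(s, SystemSpec) else SystemSpec(**s)
            for s in data["systems"]
        ]
    for key in ("cap_segment", "turn_range"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# synthetic system construction
# ---------------------------------------------------------------------------

def _system_seed(cfg: PipelineConfig, index: int) -> int:
    return int((cfg.seed * 100003 + 7919 * index + 1) % (2**31))


def build_synthetic_system(cfg: PipelineConfig, spec: SystemSpec, seed: int) -> Ensemble:
    """Generate one demo system per its planted study conditions."""
    n = cfg.n_residues
    chain = syn.ChainSpec(n, resnames=dict(_DEMO_RESNAMES))
    switch = int(round((1.0 - spec.turn_fraction) * cfg.n_frames))
    two_state = syn.TwoStateSpec(segment=cfg.cap_segment, switch_frame=switch)
    ens = syn.plant_two_state_segment(chain, two_state, cfg.n_frames, seed)

    # correlated thermal noise: cap residues move together and with the
    # 241-245 region (the communication the network stage should detect)
    cap_idx = list(range(cfg.cap_segment[0] - 1, cfg.cap_segment[1]))
    cterm_idx = list(range(240, min(245, n)))
    cov = syn.CovarianceSpec(
        base_sigma=cfg.noise_sigma,
        blocks=[(cap_idx + cterm_idx, 0.6)],
    )
    ens = syn.add_correlated_noise(ens, cov, seed + 1)

    # pseudo side-chain atoms and a substrate-like ligand
    ens = syn.add_atom(ens, 102, "OG", "O", (102, "CA"), (1.4, 0.0, 0.5))
    ens = syn.add_atom(ens, 162, "OG", "O", (162, "CA"), (1.4, 0.0, 0.5))
    ens = syn.add_atom(ens, 242, "NE2", "N", (242, "CA"), (1.2, 0.8, 0.0))
    og102 = ens.coords[0, ens.topology.index_of(102, "OG")]
    ens = syn.add_ligand(
        ens,
        "ZOL",
        300,
        [
            ("C12", "C", og102 + (0.8, 3.2, 0.0)),
            ("O2", "O", og102 + (0.0, 3.0, 0.0)),
            ("OAE", "O", og102 + (0.0, 3.5, 1.5)),
        ],
    )

    plants = syn.PlantSpec(
        hbonds=[
            syn.HbondPlant((dr, dn), (ar, an), frac)
            for dr, dn, ar, an, frac in spec.hbond_occupancies
        ],
        distances=[
            syn.DistancePlant(
                (242, "NE2"), (102, "OG"), spec.triad_distance_mean, 0.3
            ),
            syn.DistancePlant(
                (242, "NE2"), (300, "OAE"), spec.oae_distance_mean, 0.3
            ),
        ],
        angles=[
            syn.AnglePlant(
                (300, "C12"), (300, "O2"), (102, "OG"),
                spec.attack_angle_mean, 5.0,
            )
        ],
    )
    ens = syn.plant_hbonds(ens, plants, seed + 2)
    ens = syn.plant_triad_geometry(ens, plants, seed + 3)
    ens.frame_times = np.arange(cfg.n_frames) * 0.002  # ns, 2 ps spacing
    return ens


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def stage_observables(ens: Ensemble, cfg: PipelineConfig, outdir: Path) -> dict:
    bb = select_atoms(ens.topology, "backbone")
    rmsd = obs.rmsd_series(ens, 0, bb, burn_in=cfg.burn_in)
    rg = obs.rg_series(ens, burn_in=cfg.burn_in)
    sasa = obs.sasa_series(
        ens, n_points=cfg.sasa_points, burn_in=cfg.burn_in
    )
    fitted = obs.superpose(ens, 0, bb)
    rmsf = obs.rmsf_profile(fitted)
    bfac = obs.bfactor_profile(rmsf)
    series = pd.DataFrame(
        {
            "frame": np.arange(ens.n_frames),
            "rmsd": rmsd.values,
            "rg": rg.values,
            "sasa": sasa.values,
        }
    )
    _write_csv(series, outdir / "observables.csv")
    prof = rmsf.to_frame().rename(columns={"value": "rmsf"})
    prof["bfactor"] = bfac.values
    _write_csv(prof, outdir / "profiles.csv")
    return {
        "rmsd_mean": rmsd.mean,
        "rmsd_sd": rmsd.sd,
        "rg_mean": rg.mean,
        "rg_sd": rg.sd,
        "sasa_mean": sasa.mean,
        "sasa_sd": sasa.sd,
        "rmsf_resids": [int(r) for r in rmsf.resids],
        "rmsf_profile": [float(v) for v in rmsf.values],
    }


def stage_geometry(
    ens: Ensemble,
    cfg: PipelineConfig,
    outdir: Path,
    hbond_pairs: list | None = None,
) -> dict:
    top = ens.topology
    tracks = {}
    tracks["triad_dist"] = geom.distance_series(ens, (242, "NE2"), (102, "OG"))
    tracks["oae_dist"] = geom.distance_series(ens, (300, "OAE"), (242, "NE2"))
    tracks["attack_angle"] = geom.angle_series(
        ens, (300, "C12"), (300, "O2"), (102, "OG")
    )
    tracks["c12_og_dist"] = geom.distance_series(ens, (300, "C12"), (102, "OG"))
    phi, psi = geom.phi_psi(ens, 242)
    tracks["phi_242"] = phi
    tracks["psi_242"] = psi
    df = pd.DataFrame({"frame": np.arange(ens.n_frames)})
    for name, series in tracks.items():
        df[name] = series.values
    _write_csv(df, outdir / "geometry.csv")

    window = geom.window_occupancy(
        tracks["attack_angle"], cfg.attack_center, cfg.attack_halfwidth
    )
    if hbond_pairs:
        # score exactly the configured donor/acceptor pairs (Table-style)
        parts = [
            geom.hbond_occupancy(
                ens, [d], [a], cfg.hbond_distance, cfg.hbond_angle
            ).rows
            for d, a in hbond_pairs
        ]
        hb_rows = (
            pd.concat(parts, ignore_index=True)
            .sort_values("occupancy", ascending=False, kind="mergesort")
            .reset_index(drop=True)
        )
    else:
        donors = [
            i for i, a in enumerate(top.atoms)
            if 161 <= a.resid <= 165 and a.name in ("N", "OG")
        ]
        acceptors = [
            i for i, a in enumerate(top.atoms)
            if 240 <= a.resid <= 245 and a.name in ("N", "O")
        ]
        hb_rows = geom.hbond_occupancy(
            ens, donors, acceptors, cfg.hbond_distance, cfg.hbond_angle
        ).rows
    _write_csv(hb_rows, outdir / "hbonds.csv")

    track = geom.assign_ss_lite(ens)
    turn = geom.turn_occupancy(track, cfg.turn_range)
    return {
        "turn_occupancy": turn,
        "attack_window_occupancy": window,
        "triad_dist_mean": tracks["triad_dist"].mean,
        "oae_dist_mean": tracks["oae_dist"].mean,
        "attack_angle_mean": tracks["attack_angle"].mean,
        "hbond_total_occupancy": float(hb_rows["occupancy"].sum()),
    }


def _protein_only(ens: Ensemble) -> Ensemble:
    keep = [
        i for i, a in enumerate(ens.topology.atoms) if a.resname != "ZOL"
    ]
    return subset_atoms(ens, keep)


def stage_network(ens: Ensemble, cfg: PipelineConfig, outdir: Path) -> dict:
    prot = _protein_only(ens)
    ca = select_atoms(prot.topology, "name CA")
    fitted = obs.superpose_to_mean(prot, ca)
    corr = netmod.cross_correlation(fitted)
    avg = obs.average_structure(fitted)
    net = netmod.contact_network(
        avg, 0, cfg.contact_cutoff, cfg.i_min
    )
    net = netmod.weight_edges(net, corr, cfg.c_floor)
    paths = netmod.floyd_warshall(net)
    profile = netmod.degree_and_hubs(net, cfg.hub_min, paths)
    table = profile.table
    net.edges.to_csv(
        outdir / "edges.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    _write_csv(table, outdir / "nodes.csv")
    edges_b, freq = netmod.centrality_histogram(
        table["betweenness"].to_numpy(), cfg.histogram_bins
    )
    hist = pd.DataFrame(
        {"bin_left": edges_b[:-1], "bin_right": edges_b[1:], "frequency": freq}
        if len(edges_b) > 1
        else {"bin_left": [edges_b[0]], "bin_right": [edges_b[-1]], "frequency": freq}
    )
    _write_csv(hist, outdir / "betweenness_hist.csv")
    hubs = table[table["hub"]]
    top5 = table.nlargest(5, "betweenness")
    return {
        "n_edges": int(len(net.edges)),
        "n_hubs": int(len(hubs)),
        "max_degree": int(table["degree"].max()),
        "top_betweenness_resids": [int(r) for r in top5["resid"]],
        "hub_resids": [int(r) for r in hubs["resid"]],
    }


def stage_pca(ens: Ensemble, cfg: PipelineConfig, outdir: Path) -> dict:
    prot = _protein_only(ens)
    ca = select_atoms(prot.topology, "name CA")
    fitted = obs.superpose_to_mean(prot, ca)
    result = pcamod.pca(fitted)
    _write_csv(result.to_frame().head(20), outdir / "pca_modes.csv")
    proj = pd.DataFrame(
        {
            "frame": np.arange(fitted.n_frames),
            "pc1": result.projections[:, 0],
            "pc2": result.projections[:, 1],
        }
    )
    _write_csv(proj, outdir / "projections.csv")
    contrib = pcamod.residue_contribution(result, 0).rename(
        columns={"contribution": "pc1"}
    )
    contrib["pc2"] = pcamod.residue_contribution(result, 1)["contribution"]
    _write_csv(contrib, outdir / "contributions.csv")
    grid = pcamod.fel(
        result.projections[:, 0],
        result.projections[:, 1],
        cfg.fel_bins,
        cfg.temperature,
    )
    write_fel_csv(grid, outdir / "fel.csv")
    return {
        "pc1_percent": float(result.percent[0]),
        "pc2_percent": float(result.percent[1]),
    }


def write_fel_csv(grid: pcamod.FELGrid, path: Path) -> None:
    """FEL grid as a CSV matrix with bin-edge header rows."""
    with open(path, "w") as fh:
        fh.write("# units," + grid.units + "\n")
        fh.write(
            "# x_edges," + ",".join(FLOAT_FMT % v for v in grid.x_edges) + "\n"
        )
        fh.write(
            "# y_edges," + ",".join(FLOAT_FMT % v for v in grid.y_edges) + "\n"
        )
        for row in grid.delta_g:
            fh.write(
                ",".join("" if np.isnan(v) else FLOAT_FMT % v for v in row)
                + "\n"
            )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _round_floats(x, ndigits=6):
    if isinstance(x, float):
        return float(FLOAT_FMT % x)
    if isinstance(x, dict):
        return {k: _round_floats(v, ndigits) for k, v in x.items()}
    if isinstance(x, list):
        return [_round_floats(v, ndigits) for v in x]
    return x


def run_system(
    cfg: PipelineConfig, spec: SystemSpec, index: int, outdir: Path
) -> dict:
    sysdir = outdir / spec.name
    sysdir.mkdir(parents=True, exist_ok=True)
    seed = _system_seed(cfg, index)
    summary: dict = {"system": spec.name, "seed": seed}

    stage = "simulate"
    try:
        if cfg.mode == "synthetic":
            ens = build_synthetic_system(cfg, spec, seed)
            write_multimodel_pdb(ens, str(sysdir / "ensemble.pdb"))
            save_config(cfg, str(sysdir / "provenance.yaml"))
        else:
            if spec.path is None or not Path(spec.path).exists():
                raise FileNotFoundError(
                    f"input PDB not found: {spec.path!r}"
                )
            ens = read_multimodel_pdb(spec.path)
        summary["n_frames"] = ens.n_frames
        summary["n_residues"] = ens.n_residues

        pairs = [
            ((dr, dn), (ar, an))
            for dr, dn, ar, an, _frac in spec.hbond_occupancies
        ] or None
        for stage, fn, kwargs in (
            ("observables", stage_observables, {}),
            ("geometry", stage_geometry, {"hbond_pairs": pairs}),
            ("network", stage_network, {}),
            ("pca", stage_pca, {}),
        ):
            log.info("system %s: stage %s", spec.name, stage)
            summary.update(fn(ens, cfg, sysdir, **kwargs))
    except Exception as exc:
        raise PipelineError(
            f"stage '{stage}' failed for system '{spec.name}': {exc}"
        ) from exc

    # the config echo (provenance.yaml) names the output directory and is
    # deliberately not part of the reproducibility manifest
    manifest = {
        p.name: _sha256(p)
        for p in sorted(sysdir.iterdir())
        if p.suffix in (".csv", ".tsv", ".pdb")
    }
    summary["manifest"] = manifest
    summary = _round_floats(summary)
    with open(sysdir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage for every system; returns the combined report."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("resolved config: %s", cfg.to_dict())
    save_config(cfg, str(outdir / "config.yaml"))
    reports = [
        run_system(cfg, spec, k, outdir) for k, spec in enumerate(cfg.systems)
    ]
    combined = {"systems": reports}
    if len(reports) >= 2:
        comparison = compare_systems(reports)
        _write_csv(comparison, outdir / "comparison.csv")
        combined["comparison_file"] = "comparison.csv"
    with open(outdir / "report.json", "w") as fh:
        json.dump(_round_floats(combined), fh, indent=1, sort_keys=True)
    return combined


_SCALAR_METRICS = [
    "rmsd_mean", "rmsd_sd", "rg_mean", "rg_sd", "sasa_mean", "sasa_sd",
    "turn_occupancy", "attack_window_occupancy", "triad_dist_mean",
    "oae_dist_mean", "attack_angle_mean", "hbond_total_occupancy",
    "n_edges", "n_hubs", "max_degree", "pc1_percent", "pc2_percent",
]


def compare_systems(reports: list[dict]) -> pd.DataFrame:
    """Side-by-side scalar summary of >= 2 reports, plus deltas to the first.

    Raises on schema mismatch (a report missing one of the shared scalar
    metrics).
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    for rep in reports:
        missing = [m for m in _SCALAR_METRICS if m not in rep]
        if missing:
            raise ValueError(
                f"report {rep.get('system', '?')!r} lacks metrics: {missing}"
            )
    first_resids = reports[0].get("rmsf_resids")
    for rep in reports[1:]:
        if rep.get("rmsf_resids") != first_resids:
            raise ValueError(
                "schema mismatch: reports cover different residue sets"
            )
    names = [rep.get("system", f"system{k}") for k, rep in enumerate(reports)]
    rows = []
    for metric in _SCALAR_METRICS:
        row = {"metric": metric}
        for name, rep in zip(names, reports):
            row[name] = rep[metric]
        for name, rep in zip(names[1:], reports[1:]):
            row[f"delta_{name}"] = rep[metric] - reports[0][metric]
        rows.append(row)
    if first_resids is not None:
        prof0 = np.asarray(reports[0]["rmsf_profile"], dtype=float)
        row = {"metric": "rmsf_max_abs_delta"}
        for name, rep in zip(names, reports):
            prof = np.asarray(rep["rmsf_profile"], dtype=float)
            row[name] = float(np.max(np.abs(prof - prof0)))
        for name, rep in zip(names[1:], reports[1:]):
            row[f"delta_{name}"] = row[name]
        rows.append(row)
    return pd.DataFrame(rows)
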