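"""Docking-pose triage: filter cascade, dedup, pocket fit and recapture.

After a docking run every molecule carries an ordered set of poses (ligand
conformations in the receptor frame) with dimensionless scores, lower =
better.  Candidate molecules are triaged by three quantitative rules:

* **Score Rule** — the best (lowest) pose score is lower than -7.5.
* **Cluster Rule** — at least 75 % of the poses lie within 3.0 Å RMSD of the
  lowest-score pose (the reference pose itself counts).
* **Score Density Rule** — best score divided by heavy-atom count is lower
  than -0.28, a ligand-efficiency-style cut penalizing large molecules that
  score well merely through size.

Two quantified proxies for expert inspection follow: a pocket-fit fraction
(at most 30 % of heavy atoms outside the binding pocket by default) and a
greedy dedup that keeps only the better-scored of two molecules whose best
poses occupy the same space.  Finally, :func:`recapture_analysis` measures
whether re-docking a known inhibitor reproduces its crystallographic pose
among the top five scored conformations.

Ligand RMSD here uses the identity atom mapping with *no* re-superposition:
poses of one molecule share the receptor coordinate frame, and the deviation
of interest is the displacement within that frame.  Graph-automorphism
symmetry correction is deliberately not attempted (it would require chemical
perception); this slightly overestimates RMSD for symmetric ligands.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "LigandPose",
    "DockingResult",
    "FilterThresholds",
    "PocketDefinition",
    "CascadeReport",
    "RecaptureResult",
    "ligand_rmsd",
    "score_rule",
    "cluster_rule",
    "score_density_rule",
    "pocket_fit_fraction",
    "dedupe_similar",
    "run_cascade",
    "recapture_analysis",
    "read_pose_tables",
    "write_pose_tables",
    "read_pose_pdb",
    "write_pose_pdb",
]


@dataclasses.dataclass(frozen=True)
class LigandPose:
    """One docked conformation: heavy-atom coordinates plus its score."""

    pose_index: int
    score: float
    coords: np.ndarray  # (n_heavy_atoms, 3), Angstroms

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] == 0:
            raise ValueError("coords must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(c)):
            raise ValueError("coords must be finite")
        object.__setattr__(self, "coords", c)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclasses.dataclass
class DockingResult:
    """All poses of one molecule, sorted by score ascending (best first)."""

    molecule_id: str
    n_heavy_atoms: int
    poses: list[LigandPose]

    def __post_init__(self) -> None:
        if not self.poses:
            raise ValueError("DockingResult requires at least one pose")
        for p in self.poses:
            if p.n_atoms != self.n_heavy_atoms:
                raise ValueError(
                    f"{self.molecule_id}: pose {p.pose_index} has {p.n_atoms} atoms, "
                    f"expected {self.n_heavy_atoms}"
                )
        self.poses = sorted(self.poses, key=lambda p: p.score)

    @property
    def best_pose(self) -> LigandPose:
        return self.poses[0]

    @property
    def best_score(self) -> float:
        return self.poses[0].score


@dataclasses.dataclass(frozen=True)
class FilterThresholds:
    """Constants of the triage rules (defaults are the published cuts)."""

    score_cut: float = -7.5
    cluster_rmsd_cut: float = 3.0
    cluster_fraction: float = 0.75
    density_cut: float = -0.28
    pocket_out_max: float = 0.30

    def __post_init__(self) -> None:
        if not (0.0 < self.cluster_fraction <= 1.0):
            raise ValueError("cluster_fraction must lie in (0, 1]")
        if self.cluster_rmsd_cut <= 0:
            raise ValueError("cluster_rmsd_cut must be positive")


@dataclasses.dataclass(frozen=True)
class PocketDefinition:
    """Binding pocket as either a sphere or an explicit grid-point cloud."""

    center: tuple[float, float, float] | None = None
    radius: float | None = None
    grid_points: np.ndarray | None = None  # (m, 3)
    spacing: float | None = None

    def __post_init__(self) -> None:
        sphere = self.center is not None and self.radius is not None
        grid = self.grid_points is not None and self.spacing is not None
        if sphere == grid:
            raise ValueError("exactly one of sphere (center+radius) or grid (points+spacing) must be given")
        if sphere and self.radius <= 0:
            raise ValueError("radius must be positive")
        if grid:
            g = np.asarray(self.grid_points, dtype=float)
            if g.ndim != 2 or g.shape[1] != 3 or g.shape[0] == 0:
                raise ValueError("grid_points must be a non-empty (m, 3) array")
            object.__setattr__(self, "grid_points", g)


@dataclasses.dataclass
class CascadeReport:
    """Per-stage survivor accounting in molecule numbers and percentages."""

    stage_names: list[str]
    stage_counts: list[int]
    stage_percentages: list[float]  # relative to the previous stage
    per_molecule_decisions: dict[str, dict]

    def survivors(self) -> list[str]:
        return [m for m, d in self.per_molecule_decisions.items() if d["passed"]]

    def to_dict(self) -> dict:
        return {
            "stage_names": self.stage_names,
            "stage_counts": self.stage_counts,
            "stage_percentages": self.stage_percentages,
            "per_molecule_decisions": self.per_molecule_decisions,
        }


@dataclasses.dataclass
class RecaptureResult:
    """Top-pose RMSDs of a re-docked known ligand vs its X-ray conformation."""

    inhibitor_id: str
    per_pose_rmsd: list[float]
    best_rmsd: float
    recaptured: bool
    threshold: float


def ligand_rmsd(a: LigandPose, b: LigandPose) -> float:
    """Heavy-atom RMSD between two poses under the identity atom mapping.

    No re-superposition is performed: both poses are taken in the shared
    receptor frame.
    """
    if a.n_atoms != b.n_atoms:
        raise ValueError(f"atom-count mismatch: {a.n_atoms} vs {b.n_atoms}")
    d = a.coords - b.coords
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def score_rule(result: DockingResult, thresholds: FilterThresholds = FilterThresholds()) -> bool:
    """True iff the best score is strictly lower than the score cut."""
    return result.best_score < thresholds.score_cut


def cluster_rule(result: DockingResult, thresholds: FilterThresholds = FilterThresholds()) -> bool:
    """True iff the within-cut fraction of poses around the best pose reaches
    the cluster fraction (both comparisons inclusive; the reference pose
    counts in numerator and denominator)."""
    ref = result.best_pose
    n_within = sum(
        1 for p in result.poses if ligand_rmsd(p, ref) <= thresholds.cluster_rmsd_cut
    )
    return n_within / len(result.poses) >= thresholds.cluster_fraction


def score_density_rule(result: DockingResult, thresholds: FilterThresholds = FilterThresholds()) -> bool:
    """True iff best score per heavy atom is strictly lower than the cut."""
    if result.n_heavy_atoms < 1:
        raise ValueError("heavy-atom count must be at least 1")
    return result.best_score / result.n_heavy_atoms < thresholds.density_cut


def pocket_fit_fraction(pose: LigandPose, pocket: PocketDefinition) -> float:
    """Fraction of heavy atoms lying OUTSIDE the pocket.

    Sphere dialect: outside iff distance to center exceeds the radius.
    Grid dialect: outside iff the nearest grid point is farther than the
    grid spacing.
    """
    if pocket.center is not None:
        d = np.linalg.norm(pose.coords - np.asarray(pocket.center, dtype=float), axis=1)
        outside = d > pocket.radius
    else:
        d = cdist(pose.coords, pocket.grid_points).min(axis=1)
        outside = d > pocket.spacing
    return float(np.mean(outside))


def _cross_conformation_distance(a: LigandPose, b: LigandPose) -> float:
    # Mapping-free similarity between poses of *different* molecules:
    # symmetric mean of per-atom nearest-neighbor distances.
    d = cdist(a.coords, b.coords)
    return 0.5 * float(d.min(axis=1).mean() + d.min(axis=0).mean())


def dedupe_similar(candidates: Sequence[DockingResult], similarity_cut: float = 1.0) -> list[DockingResult]:
    """Keep only the better-scored of molecules whose best poses overlap.

    Candidates are processed greedily in ascending best-score order; one is
    dropped when its best pose sits within ``similarity_cut`` (symmetric mean
    nearest-neighbor distance, Å) of an already-kept candidate's best pose.
    The result is independent of the input ordering.
    """
    ordered = sorted(candidates, key=lambda r: (r.best_score, r.molecule_id))
    kept: list[DockingResult] = []
    for cand in ordered:
        if all(
            _cross_conformation_distance(cand.best_pose, k.best_pose) > similarity_cut
            for k in kept
        ):
            kept.append(cand)
    return kept


_RULES = ("score_rule", "cluster_rule", "density_rule")


def run_cascade(
    results: Sequence[DockingResult],
    thresholds: FilterThresholds = FilterThresholds(),
    pocket: PocketDefinition | None = None,
) -> CascadeReport:
    """Apply the three docking-filter rules conjunctively, then the optional
    pocket-fit stage, and account for survivors per stage.

    Percentages are survivors relative to the immediately preceding stage
    (defined as 0 when the preceding stage is empty).  Each molecule's
    decision record carries every rule verdict and the first failing rule.
    """
    if not results:
        raise ValueError("no docking results to triage")
    decisions: dict[str, dict] = {}
    autodock_pass = []
    for r in results:
        verdicts = {
            "score_rule": score_rule(r, thresholds),
            "cluster_rule": cluster_rule(r, thresholds),
            "density_rule": score_density_rule(r, thresholds),
        }
        failing = next((name for name in _RULES if not verdicts[name]), None)
        passed = failing is None
        decisions[r.molecule_id] = {**verdicts, "failing_rule": failing, "passed": passed}
        if passed:
            autodock_pass.append(r)

    stage_names = ["input", "autodock_filter"]
    stage_counts = [len(results), len(autodock_pass)]

    if pocket is not None:
        pocket_pass = []
        for r in autodock_pass:
            frac_out = pocket_fit_fraction(r.best_pose, pocket)
            ok = frac_out <= thresholds.pocket_out_max
            decisions[r.molecule_id]["pocket_fraction_out"] = frac_out
            decisions[r.molecule_id]["pocket_rule"] = ok
            if ok:
                pocket_pass.append(r)
            else:
                decisions[r.molecule_id]["failing_rule"] = "pocket_rule"
                decisions[r.molecule_id]["passed"] = False
        stage_names.append("pocket_fit")
        stage_counts.append(len(pocket_pass))

    percentages = [100.0]
    for prev, cur in zip(stage_counts, stage_counts[1:]):
        percentages.append(100.0 * cur / prev if prev else 0.0)
    return CascadeReport(stage_names, stage_counts, percentages, decisions)


def recapture_analysis(
    docked: DockingResult,
    reference: LigandPose,
    rmsd_threshold: float = 2.0,
    top_n: int = 5,
) -> RecaptureResult:
    """Compare the top-scored docked poses of a known inhibitor against its
    crystallographic conformation.

    The ligand is considered *recaptured* when the best of the (up to)
    ``top_n`` lowest-score poses lies within ``rmsd_threshold`` of the
    reference conformation.
    """
    per_pose = [ligand_rmsd(p, reference) for p in docked.poses[:top_n]]
    best = min(per_pose)
    return RecaptureResult(
        inhibitor_id=docked.molecule_id,
        per_pose_rmsd=per_pose,
        best_rmsd=best,
        recaptured=best <= rmsd_threshold,
        threshold=rmsd_threshold,
    )


# ---------------------------------------------------------------------------
# pose file dialects
# ---------------------------------------------------------------------------

def write_pose_tables(
    results: Sequence[DockingResult], scores_path: str | Path, coords_path: str | Path
) -> None:
    """Write results as the delimited two-table dialect.

    ``scores_path``: TSV with molecule_id, pose_index, score, n_heavy_atoms.
    ``coords_path``: TSV with molecule_id, pose_index, atom_index, x, y, z.
    """
    score_rows, coord_rows = [], []
    for r in results:
        for p in r.poses:
            score_rows.append((r.molecule_id, p.pose_index, p.score, r.n_heavy_atoms))
            for j, (x, y, z) in enumerate(p.coords):
                coord_rows.append((r.molecule_id, p.pose_index, j, x, y, z))
    pd.DataFrame(
        score_rows, columns=["molecule_id", "pose_index", "score", "n_heavy_atoms"]
    ).to_csv(scores_path, sep="\t", index=False)
    pd.DataFrame(
        coord_rows, columns=["molecule_id", "pose_index", "atom_index", "x", "y", "z"]
    ).to_csv(coords_path, sep="\t", index=False, float_format="%.4f")


def read_pose_tables(scores_path: str | Path, coords_path: str | Path) -> list[DockingResult]:
    """Read the delimited two-table pose dialect written by
    :func:`write_pose_tables`."""
    scores = pd.read_csv(scores_path, sep="\t", dtype={"molecule_id": str})
    coords = pd.read_csv(coords_path, sep="\t", dtype={"molecule_id": str})
    results = []
    coord_groups = {
        k: g.sort_values("atom_index")[["x", "y", "z"]].to_numpy()
        for k, g in coords.groupby(["molecule_id", "pose_index"], sort=False)
    }
    for mol_id, g in scores.groupby("molecule_id", sort=False):
        poses = []
        for row in g.itertuples(index=False):
            xyz = coord_groups.get((mol_id, row.pose_index))
            if xyz is None:
                raise ValueError(f"no coordinates for {mol_id} pose {row.pose_index}")
            poses.append(LigandPose(int(row.pose_index), float(row.score), xyz))
        results.append(DockingResult(mol_id, int(g["n_heavy_atoms"].iloc[0]), poses))
    return results


def write_pose_pdb(result: DockingResult, path: str | Path, element: str = "C") -> None:
    """Write one molecule's poses as a concatenated multi-model ligand PDB
    with the docking score in a ``REMARK SCORE`` line per model."""
    lines = []
    for m, p in enumerate(result.poses, start=1):
        lines.append(f"MODEL     {m:4d}")
        lines.append(f"REMARK SCORE {p.score:.4f}")
        for j, (x, y, z) in enumerate(p.coords, start=1):
            name = f"{element}{j}"
            lines.append(
                f"HETATM{j:5d} {name:<4s}{'LIG':>4s} A{1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pose_pdb(path: str | Path, molecule_id: str | None = None) -> DockingResult:
    """Read a concatenated multi-model ligand PDB with ``REMARK SCORE``
    records (the dialect written by :func:`write_pose_pdb`)."""
    path = Path(path)
    poses: list[LigandPose] = []
    score: float | None = None
    coords: list[list[float]] = []
    idx = 0
    for line in path.read_text().splitlines():
        if line.startswith("MODEL"):
            coords, score = [], None
        elif line.startswith("REMARK SCORE"):
            score = float(line.split()[2])
        elif line.startswith(("ATOM", "HETATM")):
            coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        elif line.startswith("ENDMDL"):
            if score is None:
                raise ValueError(f"{path}: model without a REMARK SCORE record")
            idx += 1
            poses.append(LigandPose(idx, score, np.asarray(coords)))
    if not poses:
        raise ValueError(f"{path}: no poses found")
    return DockingResult(molecule_id or path.stem, poses[0].n_atoms, poses)
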