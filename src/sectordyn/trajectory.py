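"""Trajectory ingestion, superposition, cross-correlation and dihedrals.

Coordinates live in a plain ``(frames, atoms, 3)`` array in Angstrom with a
per-atom metadata table.  Superposition uses the Kabsch least-squares fit
(proper rotations only); the dynamic cross-correlation (DCC) matrix is the
normalised covariance of per-residue positional fluctuations,

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>),

computed on one representative atom per residue (CA by default, no mass
weighting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation


class TrajectoryFormatError(ValueError):
    """Raised when trajectory input violates its declared structure."""


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates plus per-atom metadata."""

    coords: np.ndarray        # (F, N, 3) float, Angstrom
    atom_meta: pd.DataFrame   # columns: residue_number, residue_name, atom_name
    frame_stride_ps: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryFormatError("coords must have shape (F, N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryFormatError("coordinates must be finite")
        required = {"residue_number", "residue_name", "atom_name"}
        if not required.issubset(self.atom_meta.columns):
            raise TrajectoryFormatError(f"atom_meta needs columns {required}")
        if len(self.atom_meta) != self.coords.shape[1]:
            raise TrajectoryFormatError("atom_meta rows != number of atoms")
        resnums = self.atom_meta["residue_number"].to_numpy()
        if np.any(np.diff(resnums) < 0):
            raise TrajectoryFormatError("residue numbers must be non-decreasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, atom_name: str) -> "Trajectory":
        mask = (self.atom_meta["atom_name"] == atom_name).to_numpy()
        if not mask.any():
            raise KeyError(f"no atoms named {atom_name!r}")
        return Trajectory(
            self.coords[:, mask],
            self.atom_meta.loc[mask].reset_index(drop=True),
            self.frame_stride_ps,
        )

    def atom_index(self, residue_number: int, atom_name: str) -> int:
        meta = self.atom_meta
        hits = meta.index[
            (meta["residue_number"] == residue_number)
            & (meta["atom_name"] == atom_name)
        ]
        if len(hits) == 0:
            raise KeyError(
                f"atom {atom_name!r} of residue {residue_number} not found"
            )
        return int(hits[0])


@dataclass
class RigidTransform:
    rotation: np.ndarray     # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_multimodel_pdb(path: Path) -> tuple[np.ndarray, pd.DataFrame]:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))
    frames = []
    roster0 = None
    for model in structure:
        atoms = []
        coords = []
        for chain in model:
            for res in chain:
                for atom in res:
                    atoms.append(
                        (res.id[1], res.get_resname().strip(), atom.get_name())
                    )
                    coords.append(atom.get_coord())
        if roster0 is None:
            roster0 = atoms
        elif atoms != roster0:
            raise TrajectoryFormatError(
                f"model {model.id} atom roster differs from the first model"
            )
        frames.append(np.asarray(coords, dtype=float))
    if not frames:
        raise TrajectoryFormatError(f"{path}: no models found")
    meta = pd.DataFrame(
        roster0, columns=["residue_number", "residue_name", "atom_name"]
    )
    return np.stack(frames), meta


FRAME_TABLE_COLUMNS = [
    "frame", "residue_number", "residue_name", "atom_name", "x", "y", "z"
]


def _read_frame_table(path: Path) -> tuple[np.ndarray, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t")
    missing = set(FRAME_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise TrajectoryFormatError(f"{path}: missing columns {sorted(missing)}")
    frames = sorted(df["frame"].unique())
    roster0 = None
    coords = []
    for f in frames:
        sub = df[df["frame"] == f]
        roster = list(
            zip(sub["residue_number"], sub["residue_name"], sub["atom_name"])
        )
        if roster0 is None:
            roster0 = roster
        elif roster != roster0:
            raise TrajectoryFormatError(
                f"frame {f}: atom roster differs from frame {frames[0]}"
            )
        coords.append(sub[["x", "y", "z"]].to_numpy(dtype=float))
    meta = pd.DataFrame(
        roster0, columns=["residue_number", "residue_name", "atom_name"]
    )
    return np.stack(coords), meta


def read_trajectory(
    path: str | Path, format: str = "pdb", selection: str | None = None
) -> Trajectory:
    """Read a multi-model PDB or a TSV frame table as a trajectory.

    ``selection`` filters by atom name (e.g. ``"CA"``).  A single-frame file
    is accepted with a warning (insufficient for any fluctuation statistics).
    """
    path = Path(path)
    if format == "pdb":
        coords, meta = _read_multimodel_pdb(path)
    elif format == "frame-table":
        coords, meta = _read_frame_table(path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    traj = Trajectory(coords, meta)
    if selection is not None:
        traj = traj.select(selection)
    if traj.n_frames < 2:
        warnings.warn(
            "single-frame trajectory: fluctuation statistics unavailable",
            stacklevel=2,
        )
    return traj


def write_frame_table(traj: Trajectory, path: str | Path) -> None:
    F, N = traj.n_frames, traj.n_atoms
    meta = traj.atom_meta
    df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(F), N),
            "residue_number": np.tile(meta["residue_number"].to_numpy(), F),
            "residue_name": np.tile(meta["residue_name"].to_numpy(), F),
            "atom_name": np.tile(meta["atom_name"].to_numpy(), F),
            "x": traj.coords[:, :, 0].ravel(),
            "y": traj.coords[:, :, 1].ravel(),
            "z": traj.coords[:, :, 2].ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_fit(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Optimal proper rotation + translation of ``mobile`` onto ``reference``.

    Returns the transform and the post-fit RMSD in Angstrom.  Reflections are
    disallowed.  Requires >= 3 non-collinear points.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a rigid fit")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    mob_c, ref_c = mob - cm, ref - cr
    if np.linalg.matrix_rank(mob_c, tol=1e-9) < 2:
        raise ValueError("points are collinear; rotation is underdetermined")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = cr - R @ cm
    rmsd = float(rssd) / np.sqrt(n)
    return RigidTransform(rotation=R, translation=t), rmsd


def superpose_trajectory(
    traj: Trajectory,
    reference_mode: str = "mean_structure",
    fit_selection: str | None = None,
) -> Trajectory:
    """Rigid-fit every frame to a common reference.

    ``first_frame`` fits all frames to frame 0.  ``mean_structure`` (default)
    fits to frame 0, recomputes the mean structure, and refits all frames to
    that mean — the standard single refinement for fluctuation analysis.
    The fit uses ``fit_selection`` atoms (all atoms if None) but transforms
    the whole frame.
    """
    if traj.n_frames < 2:
        warnings.warn("single-frame trajectory returned unchanged", stacklevel=2)
        return traj
    if reference_mode not in ("first_frame", "mean_structure"):
        raise ValueError(f"unknown reference_mode {reference_mode!r}")

    if fit_selection is None:
        mask = np.ones(traj.n_atoms, dtype=bool)
    else:
        mask = (traj.atom_meta["atom_name"] == fit_selection).to_numpy()
        if not mask.any():
            raise KeyError(f"fit selection {fit_selection!r} matches no atoms")

    def fit_all(coords: np.ndarray, ref_pts: np.ndarray) -> np.ndarray:
        out = np.empty_like(coords)
        for f in range(coords.shape[0]):
            tf, _ = kabsch_fit(coords[f, mask], ref_pts)
            out[f] = tf.apply(coords[f])
        return out

    fitted = fit_all(traj.coords, traj.coords[0, mask])
    if reference_mode == "mean_structure":
        mean_pts = fitted[:, mask].mean(axis=0)
        fitted = fit_all(fitted, mean_pts)
    return Trajectory(fitted, traj.atom_meta.copy(), traj.frame_stride_ps)


# ---------------------------------------------------------------------------
# dynamic cross-correlation
# ---------------------------------------------------------------------------

@dataclass
class DCCMatrix:
    c: np.ndarray                 # (N_res, N_res) in [-1, 1], unit diagonal
    residue_numbers: np.ndarray

    def __post_init__(self) -> None:
        c = self.c
        if not np.allclose(c, c.T, atol=1e-9):
            raise ValueError("DCC matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-9):
            raise ValueError("DCC diagonal must be 1")
        if np.any(np.abs(c) > 1 + 1e-9):
            raise ValueError("DCC entries must lie in [-1, 1]")
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)

    def value(self, res_i: int, res_j: int) -> float:
        idx = {int(r): k for k, r in enumerate(self.residue_numbers)}
        return float(self.c[idx[res_i], idx[res_j]])


def _representative_coords(
    traj: Trajectory, representative: str
) -> tuple[np.ndarray, np.ndarray]:
    meta = traj.atom_meta
    if representative == "CA":
        mask = (meta["atom_name"] == "CA").to_numpy()
        if not mask.any():
            raise ValueError("no CA atoms present for representative selection")
        coords = traj.coords[:, mask]
        resnums = meta.loc[mask, "residue_number"].to_numpy()
    elif representative == "center_of_geometry":
        resnums = meta["residue_number"].unique()
        coords = np.stack(
            [
                traj.coords[:, (meta["residue_number"] == r).to_numpy()].mean(axis=1)
                for r in resnums
            ],
            axis=1,
        )
    else:
        raise ValueError(f"unknown representative {representative!r}")
    if len(np.unique(resnums)) != len(resnums):
        raise ValueError("more than one representative atom per residue")
    return coords, np.asarray(resnums, dtype=int)


def compute_dcc(
    traj: Trajectory,
    frame_range: tuple[int, int] | None = None,
    representative: str = "CA",
) -> DCCMatrix:
    """Normalised covariance of per-residue fluctuations across frames.

    ``frame_range`` is an inclusive pair of 0-based frame indices; default is
    all frames.  The trajectory should already be superposed.  A residue with
    zero positional variance makes its correlations undefined and raises.
    """
    coords, resnums = _representative_coords(traj, representative)
    if frame_range is not None:
        lo, hi = frame_range
        coords = coords[lo : hi + 1]
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 frames for cross-correlation")
    delta = coords - coords.mean(axis=0, keepdims=True)  # (F, N, 3)
    cov = np.einsum("fia,fja->ij", delta, delta) / delta.shape[0]
    var = np.diag(cov).copy()
    zero = var <= 0
    if np.any(zero):
        bad = resnums[zero].tolist()
        raise ValueError(f"zero fluctuation variance at residues {bad}")
    c = cov / np.sqrt(np.outer(var, var))
    c = np.clip(0.5 * (c + c.T), -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return DCCMatrix(c=c, residue_numbers=resnums)


def residue_correlation_profile(
    dcc: DCCMatrix, residue: int
) -> list[tuple[int, float]]:
    """All (partner, correlation) pairs for one residue, input order, self excluded."""
    resnums = dcc.residue_numbers
    hits = np.flatnonzero(resnums == residue)
    if len(hits) == 0:
        raise KeyError(f"residue {residue} not in DCC matrix")
    i = int(hits[0])
    return [
        (int(r), float(dcc.c[i, j]))
        for j, r in enumerate(resnums)
        if j != i
    ]


def write_dcc(dcc: DCCMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        dcc.c, index=dcc.residue_numbers, columns=dcc.residue_numbers
    )
    df.to_csv(path, sep="\t", index_label="residue")


def read_dcc(path: str | Path) -> DCCMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DCCMatrix(
        c=df.to_numpy(dtype=float),
        residue_numbers=df.index.to_numpy(dtype=int),
    )


# ---------------------------------------------------------------------------
# dihedral angles
# ---------------------------------------------------------------------------

@dataclass
class AngleSeries:
    values: np.ndarray                # degrees in (-180, 180]
    definition: list[tuple[int, str]]  # 4 (residue_number, atom_name) pairs
    frame_range: tuple[int, int]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v <= -180.0) or np.any(v > 180.0):
            raise ValueError("angles must lie in (-180, 180]")
        self.values = v


def dihedral_angles(p: np.ndarray) -> np.ndarray:
    """Signed dihedral (IUPAC convention) for (F, 4, 3) coordinates, degrees."""
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    x = np.einsum("fi,fi->f", n1, n2)
    y = np.einsum("fi,fi->f", np.cross(n1, n2), b2n)
    ang = np.degrees(np.arctan2(y, x))
    ang[ang <= -180.0] += 360.0  # wrap -180 onto +180
    return ang


_NAMED_DIHEDRALS = {
    "psi": lambda r: [(r, "N"), (r, "CA"), (r, "C"), (r + 1, "N")],
    "phi": lambda r: [(r - 1, "C"), (r, "N"), (r, "CA"), (r, "C")],
    "chi1": lambda r: [(r, "N"), (r, "CA"), (r, "CB"), (r, "OG")],
}


def dihedral_series(
    traj: Trajectory,
    spec: tuple[str, int] | list[tuple[int, str]],
    frame_range: tuple[int, int] | None = None,
) -> AngleSeries:
    """Dihedral angle time series for a named or explicit 4-atom definition.

    Named specs: ``("psi", r)`` = N(r)-CA(r)-C(r)-N(r+1); ``("phi", r)``;
    ``("chi1", r)`` = N-CA-CB-OG (serine).  Explicit specs are four
    (residue_number, atom_name) pairs.  ``frame_range`` is inclusive, 0-based.
    """
    if isinstance(spec, tuple) and len(spec) == 2 and isinstance(spec[0], str):
        name, res = spec
        if name not in _NAMED_DIHEDRALS:
            raise ValueError(f"unknown named dihedral {name!r}")
        max_res = int(traj.atom_meta["residue_number"].max())
        if name == "psi" and res >= max_res:
            raise ValueError(f"psi undefined for the last residue ({res})")
        atoms = _NAMED_DIHEDRALS[name](res)
    else:
        atoms = list(spec)
        if len(atoms) != 4:
            raise ValueError("explicit dihedral spec needs exactly 4 atoms")
    idx = [traj.atom_index(r, a) for r, a in atoms]
    coords = traj.coords[:, idx]  # (F, 4, 3)
    lo, hi = (0, traj.n_frames - 1) if frame_range is None else frame_range
    if lo < 0 or hi >= traj.n_frames or lo > hi:
        raise ValueError(f"frame range ({lo}, {hi}) outside trajectory")
    values = dihedral_angles(coords[lo : hi + 1])
    return AngleSeries(values=values, definition=atoms, frame_range=(lo, hi))


def write_angle_series(series: AngleSeries, path: str | Path) -> None:
    lo, _ = series.frame_range
    with open(path, "w") as fh:
        fh.write("frame\tdegrees\n")
        for k, v in enumerate(series.values):
            fh.write(f"{lo + k}\t{v:.4f}\n")
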