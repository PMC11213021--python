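"""Synthetic data with planted ground truth.

Two generators let every pipeline stage be exercised without external data:

* :func:`simulate_msa` plants a set of coevolving positions ("sector") in an
  otherwise-independent alignment: each sequence draws a latent state and the
  sector positions show that state's preferred residue up to a noise rate,
  emulating the covariation signature SCA detects.  A fraction of sequences
  are near-duplicates, emulating database redundancy.
* :func:`simulate_trajectory` draws per-frame residue displacements from a
  multivariate normal whose correlation is ``rho`` inside a planted network
  block and 0 elsewhere, isotropic over axes, around an extended-chain CA
  geometry — the spatial covariance is all that cross-correlation analysis
  sees, so frames are iid by default (an AR(1) knob adds time correlation).

:func:`make_linked_dataset` couples the two so the planted sector and the
planted motion network are the same residues, emulating the hypothesis that
coevolving positions move together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .msa_io import AMINO_ACIDS, Alignment
from .trajectory import Trajectory

DEFAULT_SECTOR = (7, 12, 19, 24, 33, 41)


@dataclass
class SyntheticMSAParams:
    """Planted-sector alignment model.

    Defaults are the synthetic study conditions used throughout the test
    suite: 500 sequences of length 50 with one 6-position, 2-state sector,
    5% noise and 20% near-duplicate redundancy.
    """

    n_sequences: int = 500
    length: int = 50
    sector_positions: tuple[int, ...] = DEFAULT_SECTOR  # 1-based
    n_states: int = 2
    state_profiles: np.ndarray | None = None  # (n_states, n_sector) residue idx
    noise: float = 0.05
    background: np.ndarray | None = None      # 20-vector, default uniform
    redundancy_rate: float = 0.2
    duplicate_mutation_rate: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise < 1.0:
            raise ValueError("noise must lie in [0, 1)")
        if not 0.0 <= self.redundancy_rate < 1.0:
            raise ValueError("redundancy_rate must lie in [0, 1)")
        if not 0.0 <= self.duplicate_mutation_rate <= 1.0:
            raise ValueError("duplicate_mutation_rate must lie in [0, 1]")
        if self.n_states < 2:
            raise ValueError("need at least 2 latent states")
        positions = tuple(sorted(self.sector_positions))
        if positions and not (1 <= positions[0] and positions[-1] <= self.length):
            raise ValueError("sector positions must lie in [1, length]")
        self.sector_positions = positions


def _default_profiles(
    rng: np.random.Generator, n_states: int, n_sector: int
) -> np.ndarray:
    """Distinct preferred residues across states at every sector position."""
    return np.stack(
        [
            rng.choice(len(AMINO_ACIDS), size=n_states, replace=False)
            for _ in range(n_sector)
        ],
        axis=1,
    )  # (n_states, n_sector)


def simulate_msa(
    params: SyntheticMSAParams | None = None, seed: int = 0
) -> tuple[Alignment, dict]:
    """Alignment with a planted coevolving sector; returns ground truth too.

    Per sequence a latent state is drawn uniformly; sector positions carry
    the state's preferred residue with probability ``1 - noise``, otherwise a
    background draw; all other positions are iid background.  Afterwards
    ``redundancy_rate * M`` sequences are replaced with mutated copies of
    earlier sequences (per-position substitution with
    ``duplicate_mutation_rate``).  Deterministic given ``seed``.
    """
    if params is None:
        params = SyntheticMSAParams()
    rng = np.random.default_rng(seed)
    M, L = params.n_sequences, params.length
    q = (
        np.full(20, 0.05)
        if params.background is None
        else np.asarray(params.background, float)
    )
    q = q / q.sum()
    sector = np.array(params.sector_positions, dtype=int) - 1  # 0-based columns
    profiles = (
        _default_profiles(rng, params.n_states, len(sector))
        if params.state_profiles is None
        else np.asarray(params.state_profiles, dtype=int)
    )
    if profiles.shape != (params.n_states, len(sector)):
        raise ValueError("state_profiles must be (n_states, n_sector)")
    for j in range(profiles.shape[1]):
        if len(set(profiles[:, j])) != params.n_states:
            raise ValueError(
                f"state profiles not distinct at sector position {j}"
            )

    states = rng.integers(params.n_states, size=M)
    X = rng.choice(20, size=(M, L), p=q)
    noise_mask = rng.random((M, len(sector))) < params.noise
    planted = profiles[states]  # (M, n_sector)
    X[:, sector] = np.where(noise_mask, X[:, sector], planted)

    n_dup = int(round(params.redundancy_rate * M))
    duplicate_of = np.full(M, -1, dtype=int)
    if n_dup > 0:
        originals = M - n_dup
        sources = rng.integers(originals, size=n_dup)
        for k, src in enumerate(sources):
            tgt = originals + k
            copy = X[src].copy()
            mut = rng.random(L) < params.duplicate_mutation_rate
            copy[mut] = rng.choice(20, size=int(mut.sum()), p=q)
            X[tgt] = copy
            states[tgt] = states[src]
            duplicate_of[tgt] = src

    rows = ["".join(AMINO_ACIDS[c] for c in row) for row in X]
    aln = Alignment(
        seq_ids=[f"synth_{i:05d}" for i in range(M)],
        rows=rows,
        source_format="fasta",
    )
    truth = {
        "sector_positions": [int(p) for p in params.sector_positions],
        "states": states.tolist(),
        "profiles": profiles.tolist(),
        "duplicate_of": duplicate_of.tolist(),
        "seed": int(seed),
    }
    return aln, truth


@dataclass
class SyntheticTrajParams:
    """Planted correlated-motion trajectory model."""

    n_residues: int = 50
    n_frames: int = 2000
    network_members: tuple[int, ...] = DEFAULT_SECTOR  # 1-based residues
    rho: float = 0.8
    sigma: float = 1.0          # fluctuation amplitude, Angstrom
    ca_spacing: float = 3.8     # extended-chain CA spacing, Angstrom
    rigid_noise: bool = False
    rigid_translation_sigma: float = 3.0  # Angstrom
    ar1_phi: float = 0.0        # optional frame-to-frame correlation

    def __post_init__(self) -> None:
        members = tuple(sorted(set(int(r) for r in self.network_members)))
        if members:
            if len(members) < 2:
                raise ValueError("network needs at least 2 members (or none)")
            if members[0] < 1 or members[-1] > self.n_residues:
                raise ValueError("network members must lie in [1, n_residues]")
            lower = -1.0 / (len(members) - 1)
            if not lower < self.rho <= 1.0:
                raise ValueError(
                    f"equicorrelation block of {len(members)} requires "
                    f"rho in ({lower:.4f}, 1]"
                )
        self.network_members = members
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must lie in [0, 1)")


def target_correlation_matrix(params: SyntheticTrajParams) -> np.ndarray:
    """Unit-diagonal correlation: ``rho`` inside the network block, 0 outside."""
    N = params.n_residues
    corr = np.eye(N)
    members = np.array(params.network_members, dtype=int) - 1
    if members.size:
        block = np.ix_(members, members)
        corr[block] = params.rho
        corr[members, members] = 1.0
    return corr


def simulate_trajectory(
    params: SyntheticTrajParams | None = None, seed: int = 0
) -> tuple[Trajectory, np.ndarray]:
    """CA trajectory with the planted cross-correlation structure.

    Displacements are drawn per axis from N(0, corr), scaled by ``sigma`` and
    added to an extended-chain geometry; axes are independent (isotropic).
    With ``rigid_noise`` each frame additionally receives a random rotation
    and translation, which superposition must remove.  Returns the trajectory
    and the target correlation matrix.
    """
    if params is None:
        params = SyntheticTrajParams()
    rng = np.random.default_rng(seed)
    N, F = params.n_residues, params.n_frames
    corr = target_correlation_matrix(params)
    # factor via eigendecomposition: robust for the rho=1 degenerate block
    vals, vecs = np.linalg.eigh(corr)
    factor = vecs * np.sqrt(np.clip(vals, 0.0, None))

    z = rng.standard_normal((F, N, 3))
    if params.ar1_phi > 0:
        phi = params.ar1_phi
        for f in range(1, F):
            z[f] = phi * z[f - 1] + np.sqrt(1 - phi**2) * z[f]
    disp = np.einsum("nk,fka->fna", factor, z) * params.sigma

    ref = np.zeros((N, 3))
    ref[:, 0] = params.ca_spacing * np.arange(N)
    coords = ref[None, :, :] + disp

    if params.rigid_noise:
        rots = Rotation.random(F, rng=rng)
        trans = rng.normal(scale=params.rigid_translation_sigma, size=(F, 3))
        for f in range(F):
            coords[f] = rots[f].apply(coords[f]) + trans[f]

    meta = pd.DataFrame(
        {
            "residue_number": np.arange(1, N + 1),
            "residue_name": ["ALA"] * N,
            "atom_name": ["CA"] * N,
        }
    )
    return Trajectory(coords=coords, atom_meta=meta), corr


@dataclass
class LinkedDatasetParams:
    msa: SyntheticMSAParams = field(default_factory=SyntheticMSAParams)
    traj: SyntheticTrajParams = field(default_factory=SyntheticTrajParams)

    def __post_init__(self) -> None:
        if tuple(self.msa.sector_positions) != tuple(self.traj.network_members):
            raise ValueError(
                "sector_positions and network_members must be the same set"
            )


def make_linked_dataset(
    params: LinkedDatasetParams | None = None, seed: int = 0
) -> tuple[Alignment, Trajectory, dict]:
    """MSA and trajectory sharing one planted residue network.

    Child seeds for the two generators are derived deterministically from
    ``seed``; all ground truth (sector, states, duplicates, target
    correlation) is returned as one record.
    """
    if params is None:
        params = LinkedDatasetParams()
    rng = np.random.default_rng(seed)
    seed_msa, seed_traj = (int(s) for s in rng.integers(2**31, size=2))
    aln, truth = simulate_msa(params.msa, seed=seed_msa)
    traj, corr = simulate_trajectory(params.traj, seed=seed_traj)
    truth.update(
        {
            "network_members": list(params.traj.network_members),
            "rho": params.traj.rho,
            "target_correlation": corr.tolist(),
            "seed": int(seed),
            "seed_msa": seed_msa,
            "seed_traj": seed_traj,
        }
    )
    return aln, traj, truth
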