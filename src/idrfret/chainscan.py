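"""Coarse-grained Monte Carlo chain ensembles and solution-space scanning.

A one-bead-per-residue heteropolymer with fixed bond lengths is sampled
by Metropolis Monte Carlo (pivot and crankshaft moves, kT = 1).  The
energy of a conformation decomposes into

    E_total = W_solv + U_lj + W_el

* ``U_lj`` — short-range pair potential over non-bonded pairs: a
  hydropathy-independent repulsive core (WCA form, strength
  ``repulsion_eps``) providing excluded volume, plus an attractive
  Lennard-Jones tail whose per-pair depth is ``attraction_eps`` times
  the mean normalized hydropathy of the two beads, truncated at 2.5
  bead diameters;
* ``W_el`` — screened Debye-Hueckel electrostatics
  ``q_i q_j l_B exp(-r/kappa_D) / r`` over charged pairs, with Bjerrum
  length 7.1 A (water, 298 K) and a tunable Debye length;
* ``W_solv = -lambda * n_contacts`` — the solution-repulsion term: a
  non-negative ``lambda`` rewards non-bonded contacts (r < 1.5
  diameters), so stronger repulsion of the chain by the solution drives
  compaction.  ``lambda = 0`` is the reference, most-expanding
  condition.

Scanning a lambda grid, computing the ensemble-mean radius of gyration
per condition over five independent repeats, and normalizing by the
most expanding condition yields a per-sequence compaction sensitivity.
This is a deliberately minimal stand-in for all-atom solution-space
scanning: it preserves the monotone solution-repulsion -> compaction
axis and sequence dependence through charges and hydropathy, not
atomistic energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .errors import DomainError, GeometryError, InvalidParameterError
from .seqtools import KYTE_DOOLITTLE, sequence_charges, _validate as _validate_seq

__all__ = [
    "ChainModel",
    "SolutionCondition",
    "EnergyBreakdown",
    "ScanProtocol",
    "EnsembleResult",
    "chain_energy",
    "mc_sample_ensemble",
    "radius_of_gyration",
    "solution_scan",
    "random_walk_conformation",
]

BJERRUM_LENGTH = 7.1  # Angstrom, water at 298 K

# Default scan grid: spans the model's coil-globule crossover for
# hydrophilic chains of ~40-70 residues, so the scan resolves the
# compaction transition rather than sampling only the collapsed branch.
DEFAULT_LAMBDA_GRID = (0.0, 0.2, 0.4, 0.6, 0.8)


@dataclass
class ChainModel:
    """Bead-per-residue chain: charges, hydropathies and geometry."""

    sequence: str
    charges: np.ndarray          # +1 / -1 / 0 per bead
    hydropathy: np.ndarray       # normalized [0, 1] per bead
    bond_length: float = 3.8     # Angstrom (C-alpha spacing)
    bead_diameter: float = 3.8   # Angstrom
    repulsion_eps: float = 1.0   # kT; 0 switches off excluded volume
    attraction_eps: float = 0.3  # kT at hydropathy 1

    @classmethod
    def from_sequence(cls, sequence: str, **kwargs) -> "ChainModel":
        sequence = _validate_seq(sequence)
        charges = sequence_charges(sequence).astype(float)
        hyd = np.array([(KYTE_DOOLITTLE[a] + 4.5) / 9.0 for a in sequence])
        return cls(sequence=sequence, charges=charges, hydropathy=hyd, **kwargs)

    @property
    def n_beads(self) -> int:
        return len(self.sequence)


@dataclass
class SolutionCondition:
    """One point of the solution scan; lambda = 0 is the reference."""

    lambda_repulsion: float = 0.0
    debye_length: float = 10.0      # Angstrom (~150 mM monovalent salt)
    temperature: float = 1.0        # kT units

    def __post_init__(self) -> None:
        if self.lambda_repulsion < 0:
            raise InvalidParameterError("lambda_repulsion must be >= 0")
        if self.debye_length <= 0:
            raise InvalidParameterError("debye_length must be positive")


@dataclass
class EnergyBreakdown:
    total: float
    w_solv: float
    u_lj: float
    w_el: float


@dataclass
class ScanProtocol:
    """Scaled-down sampling protocol (full-scale counts are config choices)."""

    steps: int = 100_000
    equil: int = 20_000
    snapshot_every: int = 125
    n_repeats: int = 5
    seed: int = 0
    audit_every: int = 1000

    def __post_init__(self) -> None:
        if not self.steps > self.equil >= 0:
            raise InvalidParameterError("need steps > equil >= 0")
        if self.snapshot_every < 1 or self.n_repeats < 1:
            raise InvalidParameterError("snapshot_every and n_repeats must be >= 1")


@dataclass
class EnsembleResult:
    rg_series: List[np.ndarray]        # one array of snapshot Rg per repeat
    acceptance_rates: List[float]
    max_energy_drift: float            # |incremental - recomputed| worst case
    final_coords: List[np.ndarray]

    @property
    def repeat_means(self) -> np.ndarray:
        return np.array([s.mean() for s in self.rg_series])


class _PairTables:
    """Precomputed per-pair parameters for one model + condition."""

    def __init__(self, model: ChainModel, condition: SolutionCondition):
        n = model.n_beads
        h = model.hydropathy
        self.eps_att = model.attraction_eps * 0.5 * (h[:, None] + h[None, :])
        self.qq = np.outer(model.charges, model.charges)
        self.sigma = model.bead_diameter
        self.sigma2 = self.sigma**2
        self.rmin2 = (2.0 ** (1.0 / 6.0) * self.sigma) ** 2
        self.rcut2 = (2.5 * self.sigma) ** 2
        self.rcontact2 = (1.5 * self.sigma) ** 2
        self.eps_rep = model.repulsion_eps
        self.lam = condition.lambda_repulsion
        self.kappa_d = condition.debye_length
        idx = np.arange(n)
        self.index = idx

    def pair_energy(self, r2: np.ndarray, eps_att: np.ndarray, qq: np.ndarray):
        """(u_lj, w_el, n_contacts) summed over the supplied pairs."""
        r2 = np.clip(r2, 1e-12, None)
        inv6 = (self.sigma2 / r2) ** 3
        lj_core = 4.0 * (inv6 * inv6 - inv6)
        inside_min = r2 < self.rmin2
        inside_cut = r2 < self.rcut2
        u_rep = np.where(inside_min, self.eps_rep * (lj_core + 1.0), 0.0)
        u_att = np.where(
            inside_min, -eps_att, np.where(inside_cut, eps_att * lj_core, 0.0)
        )
        u_lj = float(np.sum(u_rep + u_att))
        charged = qq != 0
        if np.any(charged):
            r = np.sqrt(r2[charged])
            w_el = float(
                np.sum(qq[charged] * BJERRUM_LENGTH * np.exp(-r / self.kappa_d) / r)
            )
        else:
            w_el = 0.0
        n_contacts = int(np.count_nonzero(r2 < self.rcontact2))
        return u_lj, w_el, n_contacts


def _check_bonds(coords: np.ndarray) -> None:
    bond_r2 = np.sum(np.diff(coords, axis=0) ** 2, axis=1)
    if np.any(bond_r2 < 1e-18):
        raise GeometryError("bonded beads overlap")


def chain_energy(
    coords: np.ndarray, model: ChainModel, condition: SolutionCondition
) -> EnergyBreakdown:
    """Full energy breakdown of one conformation (non-bonded pairs |i-j| >= 2)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (model.n_beads, 3):
        raise InvalidParameterError("coords must be (n_beads, 3)")
    _check_bonds(coords)
    tables = _PairTables(model, condition)
    iu, ju = np.triu_indices(model.n_beads, k=2)
    diff = coords[iu] - coords[ju]
    r2 = np.sum(diff * diff, axis=1)
    u_lj, w_el, n_contacts = tables.pair_energy(
        r2, tables.eps_att[iu, ju], tables.qq[iu, ju]
    )
    w_solv = -tables.lam * n_contacts
    return EnergyBreakdown(
        total=w_solv + u_lj + w_el, w_solv=w_solv, u_lj=u_lj, w_el=w_el
    )


def radius_of_gyration(coords: np.ndarray) -> float:
    """Root-mean-square bead distance from the centroid (uniform masses)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise DomainError("need at least 2 beads")
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


def random_walk_conformation(
    n_beads: int, bond_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Freely jointed random-walk conformation (uniform bond directions)."""
    v = rng.normal(size=(n_beads - 1, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    coords = np.vstack([np.zeros(3), np.cumsum(v * bond_length, axis=0)])
    return coords


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


@njit(cache=False)
def _cross_kernel(
    coords, a, b, n, eps_att, qq, sigma2, rmin2, rcut2, rcontact2,
    eps_rep, inv_debye, bjerrum,
):  # pragma: no cover - exercised through the samplers
    u_lj = 0.0
    w_el = 0.0
    n_contacts = 0
    for i in range(a, b):
        for j in range(n):
            if a <= j < b:
                continue
            d = i - j
            if -2 < d < 2:
                continue
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < 1e-12:
                r2 = 1e-12
            if r2 < rcut2:
                inv6 = (sigma2 / r2) ** 3
                core = 4.0 * (inv6 * inv6 - inv6)
                e = eps_att[i, j]
                if r2 < rmin2:
                    u_lj += eps_rep * (core + 1.0) - e
                else:
                    u_lj += e * core
                if r2 < rcontact2:
                    n_contacts += 1
            q = qq[i, j]
            if q != 0.0:
                r = np.sqrt(r2)
                w_el += q * bjerrum * np.exp(-r * inv_debye) / r
    return u_lj, w_el, n_contacts


def _cross_energy(coords: np.ndarray, moved: slice, tables: _PairTables, n: int):
    """Energy of pairs between the moved contiguous range and the rest."""
    return _cross_kernel(
        coords, moved.start, moved.stop, n,
        tables.eps_att, tables.qq,
        tables.sigma2, tables.rmin2, tables.rcut2, tables.rcontact2,
        tables.eps_rep, 1.0 / tables.kappa_d, BJERRUM_LENGTH,
    )


def _run_chain(
    model: ChainModel,
    condition: SolutionCondition,
    protocol: ScanProtocol,
    rng: np.random.Generator,
):
    n = model.n_beads
    tables = _PairTables(model, condition)
    coords = random_walk_conformation(n, model.bond_length, rng)
    energy = chain_energy(coords, model, condition).total
    kt = condition.temperature
    accepted = 0
    rgs = []
    max_drift = 0.0
    for step in range(1, protocol.steps + 1):
        if n >= 4 and rng.random() < 0.5:
            # crankshaft: rotate the interior of (i, j) about the i-j axis
            i = int(rng.integers(0, n - 2))
            j = int(rng.integers(i + 2, n))
            moved = slice(i + 1, j)
            axis = coords[j] - coords[i]
            if np.dot(axis, axis) < 1e-16:
                continue
            pivot_point = coords[i]
        else:
            # pivot: rotate one side of a random bead; move the shorter side
            p = int(rng.integers(1, n - 1))
            moved = slice(p + 1, n) if p >= n // 2 else slice(0, p)
            pivot_point = coords[p]
            axis = rng.normal(size=3)
        angle = rng.uniform(-np.pi, np.pi)
        rot = _rotation_matrix(axis, angle)
        old_lj, old_el, old_ct = _cross_energy(coords, moved, tables, n)
        new_coords = coords[moved] - pivot_point
        new_coords = new_coords @ rot.T + pivot_point
        trial = coords.copy()
        trial[moved] = new_coords
        new_lj, new_el, new_ct = _cross_energy(trial, moved, tables, n)
        d_energy = (
            (new_lj - old_lj)
            + (new_el - old_el)
            - tables.lam * (new_ct - old_ct)
        )
        if d_energy <= 0 or rng.random() < np.exp(-d_energy / kt):
            coords = trial
            energy += d_energy
            accepted += 1
        if protocol.audit_every and step % protocol.audit_every == 0:
            full = chain_energy(coords, model, condition).total
            max_drift = max(max_drift, abs(full - energy))
            energy = full
        if step > protocol.equil and (step - protocol.equil) % protocol.snapshot_every == 0:
            rgs.append(radius_of_gyration(coords))
    return np.array(rgs), accepted / protocol.steps, max_drift, coords


def mc_sample_ensemble(
    model: ChainModel,
    condition: SolutionCondition,
    protocol: Optional[ScanProtocol] = None,
    **protocol_kwargs,
) -> EnsembleResult:
    """Sample ``n_repeats`` independent Metropolis chains.

    Each repeat starts from its own seeded random-walk conformation;
    snapshots of the radius of gyration are recorded every
    ``snapshot_every`` steps after equilibration.  Pivot and crankshaft
    rotations preserve bond lengths exactly, and the incrementally
    tracked energy is audited against a full recomputation every
    ``audit_every`` steps (worst discrepancy reported).
    """
    if protocol is None:
        protocol = ScanProtocol(**protocol_kwargs)
    elif protocol_kwargs:
        protocol = replace(protocol, **protocol_kwargs)
    series, acc, coords_out = [], [], []
    max_drift = 0.0
    for rep in range(protocol.n_repeats):
        rng = np.random.default_rng([protocol.seed, rep])
        rgs, a, drift, coords = _run_chain(model, condition, protocol, rng)
        series.append(rgs)
        acc.append(a)
        coords_out.append(coords)
        max_drift = max(max_drift, drift)
    return EnsembleResult(
        rg_series=series,
        acceptance_rates=acc,
        max_energy_drift=max_drift,
        final_coords=coords_out,
    )


def solution_scan(
    model: ChainModel,
    lambda_grid: Sequence[float],
    protocol: Optional[ScanProtocol] = None,
    debye_length: float = 10.0,
) -> pd.DataFrame:
    """Ensemble-mean Rg across a lambda grid, normalized to the most
    expanding condition.

    Returns one row per condition with ``mean_rg`` (mean of the
    ``n_repeats`` repeat means), ``sd_rg`` (SD across repeat means),
    ``normalized_rg`` (mean_rg over the grid maximum, 1 at the most
    expanding condition), and the scan-level ``sensitivity``
    ``1 - min(normalized_rg)`` repeated on every row.
    """
    lambda_grid = list(lambda_grid)
    if 0.0 not in lambda_grid:
        raise InvalidParameterError("lambda_grid must include the reference 0")
    if len(lambda_grid) < 2:
        raise InvalidParameterError("sensitivity undefined for a single condition")
    if protocol is None:
        protocol = ScanProtocol()
    rows = []
    for lam in lambda_grid:
        condition = SolutionCondition(lambda_repulsion=lam, debye_length=debye_length)
        result = mc_sample_ensemble(model, condition, protocol)
        means = result.repeat_means
        rows.append(
            {
                "lambda": lam,
                "mean_rg": float(means.mean()),
                "sd_rg": float(means.std(ddof=1)) if len(means) > 1 else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    max_rg = df["mean_rg"].max()
    df["normalized_rg"] = df["mean_rg"] / max_rg
    df["sensitivity"] = 1.0 - df["normalized_rg"].min()
    return df
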