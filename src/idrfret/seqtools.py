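"""Sequence descriptors for disordered-protein scramble design.

Implements the charge-patterning parameter kappa (blob-level charge
asymmetry delta normalized by the maximally segregated arrangement
delta_max of the same composition), a helix-propensity proxy from a
shipped per-residue scale, a charge-hydropathy disorder proxy, and the
scramble-selection rule: keep composition-identical permutations with
larger kappa (less charge mixing), lower helix propensity, and preserved
disorder classification than the reference.

Kappa conventions used here: K and R are +1, D and E are -1, histidine
and everything else neutral; terminal charges are ignored; blob sizes 5
and 6; windows with no charged residues contribute sigma = 0.  delta_max
is found by exhaustive enumeration of all distinct charge arrangements
for sequences up to length 12, and for longer sequences by the best of
the six orderings of (positive block, negative block, neutral block) —
a deterministic, reproducible rule (published kappa implementations
differ in this search).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import AlphabetError, InvalidParameterError, UndefinedKappaError

__all__ = [
    "CHARGE",
    "HELIX_DDG",
    "KYTE_DOOLITTLE",
    "ChargePatternDescriptor",
    "ScrambleSelection",
    "sequence_charges",
    "charge_pattern_kappa",
    "helix_propensity_score",
    "disorder_proxy",
    "select_scrambles",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CHARGE: Dict[str, int] = {aa: 0 for aa in AMINO_ACIDS}
CHARGE.update({"K": 1, "R": 1, "D": -1, "E": -1})

# Helix-propensity free energies (kcal/mol, alanine reference; larger =
# stronger helix breaker) from the Pace & Scholtz consensus scale.
HELIX_DDG: Dict[str, float] = {
    "A": 0.00, "L": 0.21, "R": 0.21, "M": 0.24, "K": 0.26,
    "Q": 0.39, "E": 0.40, "I": 0.41, "W": 0.49, "S": 0.50,
    "Y": 0.53, "F": 0.54, "H": 0.61, "V": 0.61, "N": 0.65,
    "T": 0.66, "C": 0.68, "D": 0.69, "G": 1.00, "P": 3.16,
}

# Kyte-Doolittle hydropathy, normalized to [0, 1] on use.
KYTE_DOOLITTLE: Dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

# Charge-hydropathy boundary <R> = CH_SLOPE * <H> - CH_INTERCEPT separating
# natively disordered (above) from folded (below) sequences.
CH_SLOPE = 2.785
CH_INTERCEPT = 1.151


@dataclass
class ChargePatternDescriptor:
    f_plus: float
    f_minus: float
    fcr: float
    ncpr: float
    sigma: float
    delta: float          # mean over blob sizes
    delta_max: float      # mean over blob sizes
    kappa: float
    blob_sizes: Tuple[int, ...] = (5, 6)


@dataclass
class ScrambleSelection:
    reference: str
    candidates: List[str]
    selected: List[str]
    criteria: Dict[str, bool]
    reference_kappa: float = float("nan")
    reference_helix: float = float("nan")
    selected_kappa: List[float] = field(default_factory=list)


def _validate(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise AlphabetError(f"non-standard residues: {sorted(bad)}")
    if len(seq) < 2:
        raise InvalidParameterError("sequence must have length >= 2")
    return seq


def sequence_charges(seq: str) -> np.ndarray:
    return np.array([CHARGE[a] for a in seq], dtype=np.int8)


def _window_counts(q: np.ndarray, g: int):
    """Per-window counts of positive and negative residues (axis -1)."""
    pos = (q > 0).astype(np.int64)
    neg = (q < 0).astype(np.int64)
    cp = np.cumsum(pos, axis=-1)
    cn = np.cumsum(neg, axis=-1)
    zeros = np.zeros(q.shape[:-1] + (1,), dtype=np.int64)
    cp = np.concatenate([zeros, cp], axis=-1)
    cn = np.concatenate([zeros, cn], axis=-1)
    p = cp[..., g:] - cp[..., :-g]
    m = cn[..., g:] - cn[..., :-g]
    return p, m


def _sigma(p, m, size):
    """sigma = NCPR^2 / FCR on counts; 0 where no charged residues."""
    tot = p + m
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(tot > 0, (p - m) ** 2 / (size * tot.astype(float)), 0.0)
    return s


def _delta(q: np.ndarray, g: int) -> np.ndarray:
    """Blob-size-g charge asymmetry delta for charge vector(s) q."""
    L = q.shape[-1]
    p_tot = (q > 0).sum(axis=-1)
    m_tot = (q < 0).sum(axis=-1)
    sigma_global = _sigma(p_tot, m_tot, L)
    p, m = _window_counts(q, g)
    sigma_i = _sigma(p, m, g)
    return np.mean((sigma_i - np.expand_dims(sigma_global, -1)) ** 2, axis=-1)


def _enumerate_charge_arrangements(n_pos: int, n_neg: int, n_neu: int) -> np.ndarray:
    """All distinct arrangements of the charge multiset, as an (M, L) array."""
    from sympy.utilities.iterables import multiset_permutations

    items = [1] * n_pos + [-1] * n_neg + [0] * n_neu
    return np.array(list(multiset_permutations(items)), dtype=np.int8)


def _segregated_family(n_pos: int, n_neg: int, n_neu: int) -> np.ndarray:
    """Candidate maximally segregated arrangements.

    Two structured families whose union contains the exhaustive maximum
    for every composition up to length 12 (checked by enumeration):

    * ``[0^a, +^p, 0^m, -^q, 0^c]`` — charged blocks separated and
      flanked by neutral runs, over all splits a + m + c = n_neu;
    * ``[s^a, 0^b, t^q, 0^c, s^d]`` — one charge species split into two
      terminal runs around the other species' block, over both sign
      assignments and all splits.

    delta is invariant under global sign flip and reversal, so these
    cover their mirror images too.
    """
    rows = []
    for a in range(n_neu + 1):
        for m in range(n_neu - a + 1):
            c = n_neu - a - m
            rows.append(
                [0] * a + [1] * n_pos + [0] * m + [-1] * n_neg + [0] * c
            )
    for s_count, t_count, s, t in (
        (n_pos, n_neg, 1, -1),
        (n_neg, n_pos, -1, 1),
    ):
        if s_count < 2:
            continue
        for a in range(1, s_count):
            d = s_count - a
            for b in range(n_neu + 1):
                c = n_neu - b
                rows.append(
                    [s] * a + [0] * b + [t] * t_count + [0] * c + [s] * d
                )
    return np.array(rows, dtype=np.int8)


@lru_cache(maxsize=512)
def _delta_max(n_pos: int, n_neg: int, n_neu: int, g: int) -> float:
    L = n_pos + n_neg + n_neu
    if L <= 12:
        arrangements = _enumerate_charge_arrangements(n_pos, n_neg, n_neu)
        return float(_delta(arrangements, g).max())
    family = _segregated_family(n_pos, n_neg, n_neu)
    return float(_delta(family, g).max())


def charge_pattern_kappa(
    seq: str, blob_sizes: Sequence[int] = (5, 6)
) -> ChargePatternDescriptor:
    """Charge-patterning descriptor with kappa = mean_g delta_g / delta_max,g.

    Raises if the sequence has no charged residues (kappa undefined) or
    is shorter than the largest blob.  Compositions whose delta_max is
    zero (all windows necessarily identical, e.g. uniformly charged
    sequences) get kappa 0 by convention.
    """
    seq = _validate(seq)
    q = sequence_charges(seq)
    L = len(seq)
    n_pos = int((q > 0).sum())
    n_neg = int((q < 0).sum())
    if n_pos + n_neg == 0:
        raise UndefinedKappaError("kappa undefined: no charged residues")
    if L < max(blob_sizes):
        raise InvalidParameterError(
            f"sequence length {L} < largest blob size {max(blob_sizes)}"
        )
    f_plus, f_minus = n_pos / L, n_neg / L
    fcr = f_plus + f_minus
    ncpr = f_plus - f_minus
    sigma = ncpr**2 / fcr
    deltas, delta_maxes, ratios = [], [], []
    for g in blob_sizes:
        d = float(_delta(q[None, :], g)[0])
        dmax = _delta_max(n_pos, n_neg, L - n_pos - n_neg, g)
        deltas.append(d)
        delta_maxes.append(dmax)
        ratios.append(d / dmax if dmax > 0 else 0.0)
    return ChargePatternDescriptor(
        f_plus=f_plus,
        f_minus=f_minus,
        fcr=fcr,
        ncpr=ncpr,
        sigma=sigma,
        delta=float(np.mean(deltas)),
        delta_max=float(np.mean(delta_maxes)),
        kappa=float(np.mean(ratios)),
        blob_sizes=tuple(blob_sizes),
    )


def helix_propensity_score(seq: str, window: int = 6):
    """Sliding-window helix-propensity profile from the shipped scale.

    Per-residue scores are the negated helix-breaking free energies
    (higher = stronger helix former); the profile holds the mean over
    each length-``window`` segment and ``mean`` averages the profile.
    Intended for ranking sequences against each other only.

    Returns ``(profile, mean)``.
    """
    seq = _validate(seq)
    if window > len(seq) or window < 1:
        raise InvalidParameterError("window must be in [1, len(seq)]")
    per_res = np.array([-HELIX_DDG[a] for a in seq])
    c = np.concatenate([[0.0], np.cumsum(per_res)])
    profile = (c[window:] - c[:-window]) / window
    return profile, float(profile.mean())


def disorder_proxy(seq: str) -> dict:
    """Charge-hydropathy disorder classification (composition-only).

    A sequence is flagged disordered when its mean absolute net charge
    exceeds the boundary line ``CH_SLOPE * <H> - CH_INTERCEPT`` in
    normalized Kyte-Doolittle hydropathy <H>.  Permutation-invariant by
    construction.
    """
    seq = _validate(seq)
    q = sequence_charges(seq)
    mean_net_charge = float(abs(int(q.sum())) / len(seq))
    # composition-weighted sum so the value is exactly permutation-invariant
    counts = {a: seq.count(a) for a in set(seq)}
    mean_hydropathy = sum(
        n * (KYTE_DOOLITTLE[a] + 4.5) / 9.0 for a, n in sorted(counts.items())
    ) / len(seq)
    disordered = mean_net_charge > CH_SLOPE * mean_hydropathy - CH_INTERCEPT
    return {
        "mean_net_charge": mean_net_charge,
        "mean_hydropathy": mean_hydropathy,
        "disordered": bool(disordered),
    }


def select_scrambles(
    reference: str,
    pool: Sequence[str],
    n_keep: int = 5,
    blob_sizes: Sequence[int] = (5, 6),
    window: int = 6,
) -> ScrambleSelection:
    """Filter a scramble pool for larger kappa, lower helix score, and
    preserved disorder classification relative to the reference; rank
    survivors by kappa (descending) and keep the top ``n_keep``.

    All criteria are strict inequalities, so the reference itself never
    survives.  If fewer than ``n_keep`` candidates survive, all
    survivors are returned with a warning.
    """
    reference = _validate(reference)
    ref_kappa = charge_pattern_kappa(reference, blob_sizes).kappa
    _, ref_helix = helix_propensity_score(reference, window)
    ref_disordered = disorder_proxy(reference)["disordered"]
    survivors = []
    for cand in pool:
        cand = _validate(cand)
        if sorted(cand) != sorted(reference):
            raise InvalidParameterError(
                "pool contains a sequence with different composition"
            )
        k = charge_pattern_kappa(cand, blob_sizes).kappa
        if k <= ref_kappa:
            continue
        _, helix = helix_propensity_score(cand, window)
        if helix >= ref_helix:
            continue
        if disorder_proxy(cand)["disordered"] != ref_disordered:
            continue
        survivors.append((k, cand))
    survivors.sort(key=lambda t: -t[0])
    if len(survivors) < n_keep:
        warnings.warn(
            f"only {len(survivors)} scrambles satisfy the criteria "
            f"(requested {n_keep})",
            RuntimeWarning,
            stacklevel=2,
        )
    kept = survivors[:n_keep]
    return ScrambleSelection(
        reference=reference,
        candidates=list(pool),
        selected=[c for _, c in kept],
        criteria={
            "kappa_greater": True,
            "helix_lower": True,
            "disorder_maintained": True,
        },
        reference_kappa=ref_kappa,
        reference_helix=ref_helix,
        selected_kappa=[k for k, _ in kept],
    )
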