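"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (plate ratiometrics, TCSPC
lifetime fitting, single-cell vacuole statistics, scramble design) is
exercised against data produced here, so each generator plants an
explicit, recoverable truth:

* plate reads follow a linear-with-saturation osmolarity dose response
  with multiplicative lognormal noise on the FRET ratio;
* decay histograms are exact multinomial draws over the bin
  probabilities of a period-wrapped (40 MHz-style) exponential mixture,
  optionally IRF-convolved, so photon counts are conserved exactly;
* cell populations are fields of disk cells with dark disk vacuoles,
  whose baseline donor lifetime rises with vacuolar ratio and whose
  post-shock fractional lifetime change depends on vacuolar ratio
  through a buffering slope;
* scramble pools are uniform permutations of a reference sequence,
  preserving composition and length.

All randomness flows from one explicit integer seed per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cellquant import CellImageStack
from .errors import AlphabetError, InvalidParameterError, PlacementError
from .flim import DecayHistogram, decay_shape

__all__ = [
    "PlateTruth",
    "DecayTruth",
    "PopulationTruth",
    "gen_decay",
    "gen_plate_dataset",
    "gen_cell_population",
    "gen_scramble_pool",
    "SYNTHETIC_LEA_REFERENCE",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# Synthetic LEA-like reference sequence: hydrophilic, charge-rich and
# well-mixed (low kappa), with a helix-prone A/E/K stretch.  This is a
# designed stand-in, not any natural protein.
SYNTHETIC_LEA_REFERENCE = (
    "MAQEEKARTSEDAGKQAEEKLSDTAKGAQEDVKSTAEEKAGQTSDKAEEQAKRTGEDSAKQAEK"
)


@dataclass
class PlateTruth:
    """Planted dose response for a plate-reader experiment.

    Expected raw ratio at concentration c is
    ``baseline_ratio * (1 + slope_per_M * min(c, saturation_conc))``.
    """

    baseline_ratio: float = 1.0
    slope_per_M: float = 0.5
    saturation_conc: Optional[float] = None   # molar; None = no saturation
    noise_cv: float = 0.0
    n_replicates: int = 3
    concentrations: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0)
    total_intensity: float = 1000.0           # DxDm + DxAm, arbitrary units
    seed: int = 0

    def validate(self) -> None:
        if self.noise_cv < 0:
            raise InvalidParameterError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")
        if len(self.concentrations) == 0:
            raise InvalidParameterError("concentrations must be non-empty")
        if any(c < 0 for c in self.concentrations):
            raise InvalidParameterError("concentrations must be non-negative")


@dataclass
class DecayTruth:
    """Planted mono- or multi-exponential decay."""

    lifetimes: Sequence[float] = (3.62,)       # ns
    amplitudes: Sequence[float] = (1.0,)       # fractions, sum to 1
    total_photons: int = 100_000
    rep_period: float = 25.0                   # ns (40 MHz)
    n_bins: int = 256
    irf_sigma: float = 0.0                     # ns, 0 = no IRF
    background_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.rep_period <= 0 or self.n_bins <= 0:
            raise InvalidParameterError("rep_period and n_bins must be positive")
        if any(tau <= 0 for tau in self.lifetimes):
            raise InvalidParameterError("lifetimes must be positive")
        amps = np.asarray(self.amplitudes, dtype=float)
        if len(amps) != len(self.lifetimes):
            raise InvalidParameterError("amplitudes must match lifetimes")
        if np.any(amps < 0) or not np.isclose(amps.sum(), 1.0):
            raise InvalidParameterError("amplitudes must be >= 0 and sum to 1")
        if self.total_photons < 0:
            raise InvalidParameterError("total_photons must be >= 0")
        if not 0 <= self.background_fraction < 1:
            raise InvalidParameterError("background_fraction must be in [0, 1)")


@dataclass
class PopulationTruth:
    """Planted single-cell population for the vacuole analysis.

    Baseline lifetime per cell:
        tau0 = baseline_lifetime_intercept
               + baseline_lifetime_slope * VR + N(0, noise_sd_lifetime)
    Fractional lifetime change after shock:
        delta = -(shock_delta_mean - buffering_slope * VR)
                + N(0, noise_sd_delta)
    A negative ``buffering_slope`` therefore plants a negative
    delta-lifetime-vs-VR correlation.
    """

    n_cells: int = 100
    cell_radius_range: tuple = (8, 14)          # pixels
    vacuolar_ratio_range: tuple = (0.05, 0.45)  # fraction of cell area
    tau_donor_only: float = 3.62                # ns, unquenched donor
    baseline_lifetime_intercept: float = 2.70   # ns at VR = 0
    baseline_lifetime_slope: float = 0.90       # ns per unit VR
    shock_delta_mean: float = 0.20              # mean fractional drop at VR = 0
    buffering_slope: float = -0.25              # per unit VR (sign sets corr sign)
    noise_sd_lifetime: float = 0.212            # ns
    noise_sd_delta: float = 0.054               # fraction
    channel_noise_sd: float = 2.0               # au, per-pixel Gaussian
    image_shape: tuple = (1024, 1024)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.vacuolar_ratio_range
        if not (0 <= lo <= hi < 1):
            raise InvalidParameterError("vacuolar_ratio_range must lie in [0, 1)")
        if self.n_cells < 0:
            raise InvalidParameterError("n_cells must be >= 0")
        if self.cell_radius_range[0] <= 0:
            raise InvalidParameterError("cell radii must be positive")
        if self.tau_donor_only <= 0:
            raise InvalidParameterError("tau_donor_only must be positive")

    @classmethod
    def with_target_correlations(
        cls, r_baseline: float = 0.44, r_delta: float = -0.47, **kwargs
    ) -> "PopulationTruth":
        """Choose noise SDs so the planted population correlations equal
        the targets in expectation.

        With VR uniform on its range, corr(tau0, VR) =
        slope*sd(VR) / sqrt(slope^2 sd(VR)^2 + noise^2); solving for the
        noise gives noise = |slope|*sd(VR)*sqrt(1/r^2 - 1), and likewise
        for the delta-lifetime correlation via ``buffering_slope`` (whose
        sign must match the sign of ``r_delta``).
        """
        truth = cls(**kwargs)
        lo, hi = truth.vacuolar_ratio_range
        sd_vr = (hi - lo) / np.sqrt(12.0)
        if np.sign(truth.buffering_slope) != np.sign(r_delta):
            truth = replace(truth, buffering_slope=-truth.buffering_slope)
        if not 0 < abs(r_baseline) < 1 or not 0 < abs(r_delta) < 1:
            raise InvalidParameterError("target correlations must be in (0, 1)")
        noise_tau = abs(truth.baseline_lifetime_slope) * sd_vr * np.sqrt(
            1.0 / r_baseline**2 - 1.0
        )
        noise_delta = abs(truth.buffering_slope) * sd_vr * np.sqrt(
            1.0 / r_delta**2 - 1.0
        )
        return replace(
            truth, noise_sd_lifetime=float(noise_tau), noise_sd_delta=float(noise_delta)
        )


def gen_decay(truth: DecayTruth) -> DecayHistogram:
    """Multinomial TCSPC histogram for a planted exponential mixture.

    Bin probabilities come from oversampled evaluation of the wrapped
    (previous-pulse-corrected), optionally IRF-convolved decay shape, so
    the total count equals ``total_photons`` exactly and the draw is
    reproducible from the seed.
    """
    truth.validate()
    dt = truth.rep_period / truth.n_bins
    centers = (np.arange(truth.n_bins) + 0.5) * dt
    oversample = 16
    fine = (np.arange(truth.n_bins * oversample) + 0.5) * (dt / oversample)
    dens = np.zeros_like(fine)
    for tau, amp in zip(truth.lifetimes, truth.amplitudes):
        shape = decay_shape(fine, tau, truth.rep_period, truth.irf_sigma)
        dens += amp * shape / shape.sum()
    probs = dens.reshape(truth.n_bins, oversample).sum(axis=1)
    probs = probs / probs.sum()
    probs = (1.0 - truth.background_fraction) * probs + (
        truth.background_fraction / truth.n_bins
    )
    rng = np.random.default_rng(truth.seed)
    counts = rng.multinomial(truth.total_photons, probs)
    return DecayHistogram(
        bin_centers=centers,
        counts=counts,
        rep_period=truth.rep_period,
        irf_sigma=truth.irf_sigma,
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean lognormal multiplier(s) with coefficient of variation cv."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = np.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def gen_plate_dataset(
    truth: PlateTruth, timepoints: Sequence[float] = ()
) -> pd.DataFrame:
    """Table of plate-reader wells with a planted dose response.

    One row per (concentration, replicate, timepoint).  The noisy FRET
    ratio is the expected ratio times a unit-mean lognormal factor with
    CV ``noise_cv``; DxDm and DxAm split a constant total intensity
    consistently with that ratio, so channel arithmetic and ratio noise
    agree by construction.  Zero-concentration control wells are always
    present.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    concs = list(truth.concentrations)
    if 0.0 not in concs:
        concs = [0.0] + concs
    times = list(timepoints) if len(timepoints) else [None]
    rows = []
    for c in concs:
        c_eff = min(c, truth.saturation_conc) if truth.saturation_conc is not None else c
        expected = truth.baseline_ratio * (1.0 + truth.slope_per_M * c_eff)
        for t in times:
            for rep in range(1, truth.n_replicates + 1):
                ratio = expected * _lognormal_factor(rng, truth.noise_cv, None)
                dxdm = truth.total_intensity / (1.0 + ratio)
                dxam = truth.total_intensity - dxdm
                axam = 0.5 * truth.total_intensity * _lognormal_factor(
                    rng, truth.noise_cv, None
                )
                rows.append(
                    {
                        "well_id": f"c{c:g}_r{rep}" + (f"_t{t:g}" if t is not None else ""),
                        "DxDm": float(dxdm),
                        "DxAm": float(dxam),
                        "AxAm": float(axam),
                        "treatment": "control" if c == 0 else "treated",
                        "concentration_M": float(c),
                        "time_s": float(t) if t is not None else 0.0,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def _place_disks(
    rng: np.random.Generator, truth: PopulationTruth, gap: float = 3.0
):
    """Rejection-sample non-overlapping disk centres and radii."""
    h, w = truth.image_shape
    r_lo, r_hi = truth.cell_radius_range
    centers, radii = [], []
    max_tries = 2000 * max(truth.n_cells, 1)
    tries = 0
    while len(centers) < truth.n_cells:
        if tries > max_tries:
            raise PlacementError(
                f"placed {len(centers)}/{truth.n_cells} cells in {max_tries} tries"
            )
        tries += 1
        r = rng.uniform(r_lo, r_hi)
        cy = rng.uniform(r + 2, h - r - 2)
        cx = rng.uniform(r + 2, w - r - 2)
        ok = True
        for (oy, ox), orad in zip(centers, radii):
            if (cy - oy) ** 2 + (cx - ox) ** 2 < (r + orad + gap) ** 2:
                ok = False
                break
        if ok:
            centers.append((cy, cx))
            radii.append(r)
    return centers, radii


def gen_cell_population(truth: PopulationTruth):
    """Synthetic field of yeast-like cells before and after osmotic shock.

    Returns ``(stack_pre, stack_post, ground_truth)`` where the stacks
    carry DxDm/DxAm/AxAm channels plus a per-pixel donor-lifetime image,
    and the table holds the planted per-cell geometry, baseline lifetime,
    and fractional lifetime change.  Channel intensities are consistent
    with the lifetime through E = 1 - tau/tau_donor_only, a constant
    donor-excitation total split between DxDm and DxAm.  Vacuoles exclude
    the sensor and appear dark in every channel.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    h, w = truth.image_shape
    shape = (h, w)
    background = 5.0
    cyto_axam = 200.0
    cyto_total_donor = 300.0

    def empty_stack():
        z = np.full(shape, background, dtype=float)
        return CellImageStack(
            DxDm=z.copy(), DxAm=z.copy(), AxAm=z.copy(),
            lifetime=np.zeros(shape), pixel_size=0.24, z_planes=1,
        )

    columns = [
        "cell_id", "center_row", "center_col", "radius", "vacuole_radius",
        "vacuolar_ratio", "tau_baseline", "delta_lifetime", "tau_post",
    ]
    if truth.n_cells == 0:
        return empty_stack(), empty_stack(), pd.DataFrame(columns=columns)

    centers, radii = _place_disks(rng, truth)
    lo, hi = truth.vacuolar_ratio_range
    vrs = rng.uniform(lo, hi, size=truth.n_cells)
    tau0 = (
        truth.baseline_lifetime_intercept
        + truth.baseline_lifetime_slope * vrs
        + rng.normal(0.0, truth.noise_sd_lifetime, size=truth.n_cells)
    )
    tau0 = np.clip(tau0, 0.3, None)
    delta = (
        -(truth.shock_delta_mean - truth.buffering_slope * vrs)
        + rng.normal(0.0, truth.noise_sd_delta, size=truth.n_cells)
    )
    tau_post = np.clip(tau0 * (1.0 + delta), 0.3, None)

    rr, cc = np.mgrid[0:h, 0:w]
    stacks = []
    for taus in (tau0, tau_post):
        dxdm = np.full(shape, background, dtype=float)
        dxam = np.full(shape, background, dtype=float)
        axam = np.full(shape, background, dtype=float)
        tau_img = np.zeros(shape)
        for i, ((cy, cx), rad) in enumerate(zip(centers, radii)):
            vac_r = rad * np.sqrt(vrs[i])
            d2 = (rr - cy) ** 2 + (cc - cx) ** 2
            cell = d2 <= rad**2
            vac = d2 <= vac_r**2
            cyto = cell & ~vac
            eff = float(np.clip(1.0 - taus[i] / truth.tau_donor_only, 0.02, 0.95))
            dxdm[cyto] = background + cyto_total_donor * (1.0 - eff)
            dxam[cyto] = background + cyto_total_donor * eff
            axam[cyto] = background + cyto_axam
            tau_img[cyto] = taus[i]
        if truth.channel_noise_sd > 0:
            dxdm = np.clip(dxdm + rng.normal(0, truth.channel_noise_sd, shape), 0, None)
            dxam = np.clip(dxam + rng.normal(0, truth.channel_noise_sd, shape), 0, None)
            axam = np.clip(axam + rng.normal(0, truth.channel_noise_sd, shape), 0, None)
        stacks.append(
            CellImageStack(
                DxDm=dxdm, DxAm=dxam, AxAm=axam, lifetime=tau_img,
                pixel_size=0.24, z_planes=1,
            )
        )

    table = pd.DataFrame(
        {
            "cell_id": np.arange(1, truth.n_cells + 1),
            "center_row": [c[0] for c in centers],
            "center_col": [c[1] for c in centers],
            "radius": radii,
            "vacuole_radius": [r * np.sqrt(v) for r, v in zip(radii, vrs)],
            "vacuolar_ratio": vrs,
            "tau_baseline": tau0,
            "delta_lifetime": delta,
            "tau_post": tau_post,
        },
        columns=columns,
    )
    return stacks[0], stacks[1], table


def gen_scramble_pool(sequence: str, n: int, seed: int = 0) -> list:
    """``n`` independent uniform permutations of ``sequence``.

    Each output keeps the exact residue multiset and length of the
    input; permutations are drawn by Fisher-Yates shuffling.
    """
    if len(sequence) < 2:
        raise InvalidParameterError("sequence must have length >= 2")
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise AlphabetError(f"non-standard residues: {sorted(bad)}")
    if n < 0:
        raise InvalidParameterError("n must be >= 0")
    rng = np.random.default_rng(seed)
    letters = np.array(list(sequence))
    return ["".join(rng.permutation(letters)) for _ in range(n)]
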