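"""Synthetic data generators with known ground truth.

Every downstream stage of the package (image correction, pixel-distribution
statistics, survival analysis, metabolomics, enrichment) is exercised against
data produced here, so each generator returns both the observable data and the
latent truth it was built from.  The truth objects are for oracle tests only;
no analysis stage reads them.

The imaging generator implements the forward model whose inverse is the
correction chain in :mod:`dormaflux.correction`:

    probe      = G * B * (S + A) + D + noise
    background = G * B * A       + D + noise
    dark       =                   D + noise
    phantom    = G * B * C_ph    + D + noise
    rhodamine  = G * B * C_rho   + D + noise

with day gain ``G``, peak-normalized beam profile ``B(x, y)``, true signal
field ``S``, autofluorescence ``A``, dark offset ``D`` and Gaussian noise
whose SD scales with the square root of the expected counts (a Poisson–
Gaussian CCD approximation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .correction import ImagingSession
from .survival import VolumeTrajectory

__all__ = [
    "PhaseProfile",
    "SessionParams",
    "SessionTruth",
    "CohortParams",
    "MetabolomicsDesign",
    "MetaboliteTable",
    "PHASE_PROFILES",
    "FAST_LINE",
    "SLOW_LINE",
    "ETOMOXIR_ARM",
    "DEFAULT_PLANTED_EFFECTS",
    "generate_imaging_session",
    "generate_volume_cohort",
    "generate_metabolomics",
    "generate_expression",
]

# Volume of the 5 x 5 mm dox-withdrawal trigger, V = L * W^2 / 2.
TRIGGER_VOLUME_MM3 = 62.5


# ---------------------------------------------------------------------------
# Imaging sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseProfile:
    """Ordinal description of one probe at one phase of the dormancy cycle.

    ``mean_signal`` is the mean of the true signal field over the whole field
    of view (calibrated units), ``dispersion`` the coefficient of variation of
    the signal within its covered area, ``coverage_fraction`` the fraction of
    the field carrying signal, and ``spatial_corr_len`` the correlation length
    of the field in pixels.
    """

    phase: str  # primary | regression | dormancy | recurrence
    probe: str  # NBDG | TMRE
    mean_signal: float
    dispersion: float = 0.35
    coverage_fraction: float = 0.7
    spatial_corr_len: float = 8.0
    # Dim diffuse signal underlying the whole field (fraction of mean_signal).
    # Tumor tissue fluoresces everywhere; coverage_fraction controls where the
    # strong, heterogeneous probe uptake sits on top of this floor.
    signal_floor: float = 0.2

    def __post_init__(self) -> None:
        if self.phase not in {"primary", "regression", "dormancy", "recurrence"}:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.probe not in {"NBDG", "TMRE"}:
            raise ValueError(f"unknown probe {self.probe!r}")
        if self.mean_signal < 0:
            raise ValueError("mean_signal must be >= 0")
        if not 0 < self.coverage_fraction <= 1:
            raise ValueError("coverage_fraction must be in (0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.signal_floor < 1:
            raise ValueError("signal_floor must be in [0, 1)")


@dataclass(frozen=True)
class SessionParams:
    """Instrument-side parameters of the forward model."""

    shape: tuple[int, int] = (256, 256)
    day_gain: float = 1.0
    dark_offset: float = 100.0
    autofluorescence: float = 120.0
    phantom_level: float = 8000.0
    rhodamine_level: float = 6000.0
    beam_fwhm_frac: float = 1.0  # beam FWHM as a fraction of the field width
    noise_scale: float = 1.0  # 0 disables noise entirely

    def __post_init__(self) -> None:
        if self.day_gain <= 0:
            raise ValueError("day_gain must be > 0")
        if self.dark_offset < 0:
            raise ValueError("dark_offset must be >= 0")
        if min(self.shape) < 64:
            raise ValueError("image dimensions must be >= 64 x 64")
        if self.phantom_level <= 0 or self.rhodamine_level <= 0:
            raise ValueError("phantom and rhodamine levels must be > 0")


@dataclass
class SessionTruth:
    """Latent state behind one generated imaging session."""

    true_signal_field: np.ndarray
    day_gain: float
    beam_profile: np.ndarray
    dark_offset: float
    autofluorescence: float


def _gaussian_beam(shape: tuple[int, int], fwhm_frac: float) -> np.ndarray:
    """Peak-normalized 2-D Gaussian beam with FWHM = fwhm_frac * width."""
    ny, nx = shape
    y = np.arange(ny) - (ny - 1) / 2.0
    x = np.arange(nx) - (nx - 1) / 2.0
    sigma = fwhm_frac * nx / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    r2 = y[:, None] ** 2 + x[None, :] ** 2
    return np.exp(-r2 / (2.0 * sigma**2))


def _smooth_standard_field(shape, corr_len, rng):
    """Gaussian-smoothed white noise, re-standardized to mean 0 / SD 1."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=corr_len)
    sd = z.std()
    if sd == 0:
        return np.zeros(shape)
    return (z - z.mean()) / sd


def _signal_field(profile: PhaseProfile, shape, rng) -> np.ndarray:
    """Nonnegative, spatially correlated field with the profile's mean, CV
    and coverage fraction (mean taken over the whole field).

    The heterogeneous (masked, log-normal) component rides on a dim uniform
    floor of ``signal_floor * mean_signal``; the mix keeps the whole-field
    mean exactly ``mean_signal``.
    """
    cov = profile.coverage_fraction
    floor = profile.signal_floor
    mean_inside = profile.mean_signal / cov
    amp = _smooth_standard_field(shape, profile.spatial_corr_len, rng)
    if profile.dispersion > 0:
        sigma = math.sqrt(math.log(1.0 + profile.dispersion**2))
        mu = math.log(mean_inside) - sigma**2 / 2.0 if mean_inside > 0 else -np.inf
        values = np.exp(mu + sigma * amp) if mean_inside > 0 else np.zeros(shape)
    else:
        values = np.full(shape, mean_inside)
    if cov < 1.0:
        # independent field decides which pixels carry strong signal; the
        # empirical quantile threshold makes realized coverage exact up to
        # pixel quantization
        mask_field = _smooth_standard_field(shape, profile.spatial_corr_len, rng)
        thr = np.quantile(mask_field, 1.0 - cov)
        values = np.where(mask_field > thr, values, 0.0)
    return floor * profile.mean_signal + (1.0 - floor) * values


def generate_imaging_session(
    profile: PhaseProfile,
    params: SessionParams = SessionParams(),
    seed: int = 0,
    *,
    mouse_id: str = "m0",
    timepoint: str | None = None,
) -> tuple[ImagingSession, SessionTruth]:
    """Generate the five raw frames of one probe/timepoint acquisition.

    Returns the observable :class:`~dormaflux.correction.ImagingSession` and
    the :class:`SessionTruth` it was synthesized from.
    """
    rng = np.random.default_rng(seed)
    shape = params.shape
    S = _signal_field(profile, shape, rng)
    B = _gaussian_beam(shape, params.beam_fwhm_frac)
    G, A, D = params.day_gain, params.autofluorescence, params.dark_offset

    def frame(expected: np.ndarray | float) -> np.ndarray:
        expected = np.broadcast_to(np.asarray(expected, dtype=float), shape)
        if params.noise_scale == 0:
            return expected.copy()
        sd = params.noise_scale * np.sqrt(np.clip(expected, 0.0, None))
        return expected + rng.standard_normal(shape) * sd

    session = ImagingSession(
        probe_frame=frame(G * B * (S + A) + D),
        dark_frame=frame(D),
        background_frame=frame(G * B * A + D),
        phantom_frame=frame(G * B * params.phantom_level + D),
        rhodamine_frame=frame(G * B * params.rhodamine_level + D),
        probe=profile.probe,
        mouse_id=mouse_id,
        timepoint=timepoint or profile.phase,
    )
    truth = SessionTruth(
        true_signal_field=S,
        day_gain=G,
        beam_profile=B,
        dark_offset=D,
        autofluorescence=A,
    )
    return session, truth


# Ordinal phase-profile defaults.  Numeric values are generator choices tuned
# only to reproduce the ordinal relations seen in vivo: 2-NBDG falls after
# oncogene ablation (and, in the slow line only, rebounds at recurrence);
# TMRE rises through regression/dormancy/recurrence and progressively covers
# more of the field.
PHASE_PROFILES: dict[tuple[str, str, str], PhaseProfile] = {}
_PROFILE_TABLE = {
    # (line, probe): {phase: (mean_signal, coverage_fraction)}
    ("fast", "NBDG"): {
        "primary": (2400.0, 0.75),
        "regression": (1240.0, 0.65),
        "dormancy": (1160.0, 0.60),
        "recurrence": (1240.0, 0.65),
    },
    ("fast", "TMRE"): {
        "primary": (1200.0, 0.50),
        "regression": (2000.0, 0.70),
        "dormancy": (2200.0, 0.80),
        "recurrence": (2400.0, 0.90),
    },
    ("slow", "NBDG"): {
        "primary": (2400.0, 0.75),
        "regression": (1400.0, 0.65),
        "dormancy": (1320.0, 0.60),
        "recurrence": (2240.0, 0.75),
    },
    ("slow", "TMRE"): {
        "primary": (1200.0, 0.50),
        "regression": (1920.0, 0.70),
        "dormancy": (2080.0, 0.80),
        "recurrence": (2480.0, 0.90),
    },
}
for (_line, _probe), _phases in _PROFILE_TABLE.items():
    for _phase, (_mean, _cov) in _phases.items():
        PHASE_PROFILES[(_line, _probe, _phase)] = PhaseProfile(
            phase=_phase, probe=_probe, mean_signal=_mean, coverage_fraction=_cov
        )


# ---------------------------------------------------------------------------
# Tumor-volume cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortParams:
    """Parameters of one cohort's latent volume trajectories.

    Latent model per mouse, with day 0 = dox withdrawal at the 5 x 5 mm
    trigger (V0 = 62.5 mm^3): exponential decay with half-life
    ``regression_halflife`` down to ``residual_fraction * V0`` (the dormancy
    plateau, reached at the nadir day), then a flat plateau until the
    mouse-specific recurrence day (log-normal around
    ``median_recurrence_day`` with log-scale SD ``recurrence_spread``), then
    exponential regrowth at ``regrowth_rate``.  Calipers are read 3x/week
    with multiplicative log-normal noise of CV ``measurement_noise_cv``.
    """

    n_mice: int = 11
    growth_rate: float = 0.25  # /day, pre-withdrawal (metadata; day >= 0 only)
    regression_halflife: float = 3.0  # days
    residual_fraction: float = 0.20
    median_recurrence_day: float = 55.0
    recurrence_spread: float = 0.10  # log-scale SD
    regrowth_rate: float = 0.25  # /day
    measurement_noise_cv: float = 0.10
    measurement_days_per_week: int = 3
    followup_days: float = 150.0
    arm: str = "control"

    def __post_init__(self) -> None:
        if self.n_mice < 2:
            raise ValueError("n_mice must be >= 2")
        if not 0 < self.residual_fraction < 1:
            raise ValueError("residual_fraction must be in (0, 1)")
        if self.median_recurrence_day <= 0:
            raise ValueError("median_recurrence_day must be > 0")
        if self.median_recurrence_day <= self.nadir_day:
            raise ValueError(
                "median_recurrence_day must exceed the time to nadir "
                f"({self.nadir_day:.1f} d); recurrence before dormancy is "
                "unidentifiable"
            )

    @property
    def nadir_day(self) -> float:
        """Day at which the decay reaches the residual plateau."""
        return self.regression_halflife * math.log2(1.0 / self.residual_fraction)


# Cohort presets.  Fast line: ~80% regression within a week, recurrence
# around day 55.  Slow line: nadir around day 28, recurrence around day 100.
# Etomoxir arm: fast-line control parameters with the median recurrence day
# scaled by 1.59 (a ~59% RFS extension).
FAST_LINE = CohortParams()
SLOW_LINE = CohortParams(
    regression_halflife=12.0,
    median_recurrence_day=100.0,
    followup_days=220.0,
    arm="slow",
)
ETOMOXIR_ARM = replace(
    FAST_LINE,
    median_recurrence_day=FAST_LINE.median_recurrence_day * 1.59,
    followup_days=200.0,
    arm="etomoxir",
)


def _measurement_days(params: CohortParams) -> np.ndarray:
    """3-per-week caliper grid (Mon/Wed/Fri pattern) from day 0."""
    if params.measurement_days_per_week == 3:
        offsets = np.array([0, 2, 4])
    else:
        offsets = np.round(
            np.linspace(0, 7, params.measurement_days_per_week, endpoint=False)
        ).astype(int)
    weeks = np.arange(0, int(params.followup_days // 7) + 2) * 7
    days = (weeks[:, None] + offsets[None, :]).ravel()
    return days[days <= params.followup_days].astype(float)


def _latent_volume(t: np.ndarray, params: CohortParams, recurrence_day: float) -> np.ndarray:
    decay = np.exp(-math.log(2.0) * t / params.regression_halflife)
    v = TRIGGER_VOLUME_MM3 * np.maximum(decay, params.residual_fraction)
    regrow = t > recurrence_day
    plateau = TRIGGER_VOLUME_MM3 * params.residual_fraction
    v = np.where(
        regrow, plateau * np.exp(params.regrowth_rate * (t - recurrence_day)), v
    )
    return v


def generate_volume_cohort(
    params: CohortParams = FAST_LINE,
    dox_withdrawal_day: float = 0.0,
    seed: int = 0,
) -> list[VolumeTrajectory]:
    """Generate per-mouse caliper trajectories for one cohort.

    Days are reported relative to dox withdrawal.  Each trajectory carries
    ``true_recurrence_day`` as latent ground truth; the survival stage never
    reads it.
    """
    rng = np.random.default_rng(seed)
    days = _measurement_days(params) + dox_withdrawal_day
    sigma = math.sqrt(math.log(1.0 + params.measurement_noise_cv**2))
    trajectories: list[VolumeTrajectory] = []
    for i in range(params.n_mice):
        t_rec = params.median_recurrence_day * math.exp(
            params.recurrence_spread * rng.standard_normal()
        )
        t_rec = max(t_rec, params.nadir_day + 1e-9)
        latent = _latent_volume(days - dox_withdrawal_day, params, t_rec)
        if sigma > 0:
            observed = latent * np.exp(sigma * rng.standard_normal(latent.shape))
        else:
            observed = latent.copy()
        # back-compute caliper axes: per-mouse aspect ratio, V = L * W^2 / 2
        aspect = rng.uniform(1.0, 1.3)
        widths = np.cbrt(2.0 * observed / aspect)
        lengths = aspect * widths
        trajectories.append(
            VolumeTrajectory(
                mouse_id=f"{params.arm}_{i:03d}",
                arm=params.arm,
                days=days,
                lengths=lengths,
                widths=widths,
                true_recurrence_day=t_rec,
            )
        )
    return trajectories


# ---------------------------------------------------------------------------
# Metabolomics tables
# ---------------------------------------------------------------------------

_ACYLCARNITINES = [f"C{n}" for n in range(2, 21)] + [
    "C4:1", "C5:1", "C6:1", "C8:1", "C10:1", "C12:1", "C14:1", "C14:2",
    "C16:1", "C16:2", "C18:1", "C18:2", "C20:1", "C20:4", "C5-OH", "C4-DC",
    "C6-DC", "C8-DC", "C10-DC", "C12-OH", "C14-OH", "C16-OH", "C18-OH",
    "C18:1-OH", "C18:2-OH", "C22",
]
_AMINO_ACIDS = [
    "Alanine", "Arginine", "Aspartate", "Citrulline", "Glutamate", "Glycine",
    "Histidine", "Leucine/Isoleucine", "Methionine", "Ornithine",
    "Phenylalanine", "Proline", "Serine", "Tyrosine", "Valine",
]
_ORGANIC_ACIDS = [
    "Lactate", "Pyruvate", "Citrate", "Succinate", "Fumarate", "Malate",
    "Alpha-ketoglutarate", "3-Hydroxybutyrate", "Acetoacetate",
]
_CLASS_POOLS = {
    "acylcarnitine": _ACYLCARNITINES,
    "amino acid": _AMINO_ACIDS,
    "organic acid": _ORGANIC_ACIDS,
}

# Default effect template for the treated-vs-control regression comparison:
# fatty-acid-oxidation blockade depletes 8 (mostly long-chain) acylcarnitines
# and 2 amino acids.  All planted magnitudes clear the |log2FC| > 1 volcano
# gate with margin.
DEFAULT_PLANTED_EFFECTS: tuple[tuple[str, float], ...] = (
    ("C12", -1.5), ("C14", -1.7), ("C16", -2.8), ("C16:1", -2.3),
    ("C18", -2.0), ("C18:1", -2.5), ("C18:2", -2.2), ("C20", -1.6),
    ("Glutamate", -1.8), ("Alanine", -1.5),
)


@dataclass(frozen=True)
class MetabolomicsDesign:
    """Design of a two-group targeted metabolomics experiment."""

    n_per_group: int = 5
    metabolite_classes: dict[str, int] = field(
        default_factory=lambda: {"acylcarnitine": 45, "amino acid": 15, "organic acid": 9}
    )
    planted_effects: tuple[tuple[str, float], ...] = DEFAULT_PLANTED_EFFECTS
    missing_rate: float = 0.05
    within_group_cv: float = 0.20
    groups: tuple[str, str] = ("etomoxir", "control")  # (treated, reference)

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        names = set(self.metabolite_names())
        for met, _ in self.planted_effects:
            if met not in names:
                raise ValueError(f"planted metabolite {met!r} not in the class map")

    def metabolites(self) -> list[tuple[str, str]]:
        """(name, class) pairs; named from curated per-class pools, padded
        with generic names if a class count exceeds its pool."""
        out: list[tuple[str, str]] = []
        for cls, count in self.metabolite_classes.items():
            pool = list(_CLASS_POOLS.get(cls, []))
            pool += [f"{cls}_{i}" for i in range(max(0, count - len(pool)))]
            out.extend((name, cls) for name in pool[:count])
        return out

    def metabolite_names(self) -> list[str]:
        return [name for name, _ in self.metabolites()]


@dataclass
class MetaboliteTable:
    """Samples x metabolites abundance matrix with class/group annotations."""

    abundances: pd.DataFrame  # index = samples, columns = metabolites
    metabolite_class: pd.Series  # per metabolite
    group: pd.Series  # per sample
    provenance: list[str] = field(default_factory=list)
    truth: pd.DataFrame | None = None  # planted log2 effects (oracle only)

    def copy(self) -> "MetaboliteTable":
        return MetaboliteTable(
            abundances=self.abundances.copy(),
            metabolite_class=self.metabolite_class.copy(),
            group=self.group.copy(),
            provenance=list(self.provenance),
            truth=None if self.truth is None else self.truth.copy(),
        )


def generate_metabolomics(
    design: MetabolomicsDesign = MetabolomicsDesign(), seed: int = 0
) -> MetaboliteTable:
    """Generate a two-group metabolite table with planted log2 effects.

    Abundances are log-normal around metabolite-specific base levels; the
    first group listed in ``design.groups`` is the treated group and receives
    the planted shifts.  Missing cells are injected completely at random.
    """
    rng = np.random.default_rng(seed)
    pairs = design.metabolites()
    names = [name for name, _ in pairs]
    classes = pd.Series({name: cls for name, cls in pairs}).reindex(names)
    n = design.n_per_group
    treated, control = design.groups
    samples = [f"{treated}_{i + 1}" for i in range(n)] + [
        f"{control}_{i + 1}" for i in range(n)
    ]
    group = pd.Series([treated] * n + [control] * n, index=samples)

    base = np.exp(rng.normal(math.log(10.0), 1.0, size=len(names)))  # uM-scale
    effects = dict(design.planted_effects)
    shift = np.array([2.0 ** effects.get(m, 0.0) for m in names])
    sigma = math.sqrt(math.log(1.0 + design.within_group_cv**2))
    mu = np.log(base) - sigma**2 / 2.0
    noise = rng.standard_normal((2 * n, len(names)))
    values = np.exp(mu[None, :] + sigma * noise)
    values[:n, :] *= shift[None, :]

    abundances = pd.DataFrame(values, index=samples, columns=names)
    if design.missing_rate > 0:
        mask = rng.random(abundances.shape) < design.missing_rate
        abundances = abundances.mask(mask)
    truth = pd.DataFrame(
        {
            "metabolite": names,
            "class": classes.values,
            "log2_effect": [effects.get(m, 0.0) for m in names],
        }
    )
    return MetaboliteTable(
        abundances=abundances,
        metabolite_class=classes,
        group=group,
        provenance=["generated"],
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def generate_expression(
    n_genes: int = 2000,
    geneset_size: int = 50,
    effect: float = 1.0,
    n_per_group: int = 5,
    seed: int = 0,
    *,
    groups: tuple[str, str] = ("primary", "regression"),
    within_group_cv: float = 0.30,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Generate a genes x samples expression matrix with one enriched set.

    Member genes receive a mean log2 shift ``effect`` in the first group.
    Returns ``(matrix, sample_groups, member_gene_ids)``.
    """
    if geneset_size <= 0:
        raise ValueError("geneset_size must be >= 1")
    if geneset_size >= n_genes:
        raise ValueError("geneset_size must be < n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    members = list(rng.choice(genes, size=geneset_size, replace=False))
    a, b = groups
    samples = [f"{a}_{i + 1}" for i in range(n_per_group)] + [
        f"{b}_{i + 1}" for i in range(n_per_group)
    ]
    sample_groups = pd.Series([a] * n_per_group + [b] * n_per_group, index=samples)

    base = np.exp(rng.normal(math.log(100.0), 1.5, size=n_genes))
    sigma = math.sqrt(math.log(1.0 + within_group_cv**2))
    values = np.exp(
        np.log(base)[:, None]
        - sigma**2 / 2.0
        + sigma * rng.standard_normal((n_genes, 2 * n_per_group))
    )
    member_idx = [genes.index(g) for g in members]
    values[np.array(member_idx)[:, None], : n_per_group] *= 2.0**effect
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    return matrix, sample_groups, members
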