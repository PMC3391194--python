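"""Seeded generators for every analysis stage, with ground truth attached.

Each generator is a pure function of its truth record (including the seed):
identical truth records produce identical outputs.  Truth records carry
everything needed to compute the expected value of every downstream
statistic, so parameter-recovery tests never need external data.

The kinetics defaults mirror a low-activity deacetylase assayed by a
quenched-FRET peptide assay: k_cat on the order of 1e-3 min^-1, apparent
K_m of ~15 µM for the peptide and ~50 µM for NAD+, measured with the
co-substrate held at a fixed reference concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sirtflow.frap import FrapTrace
from sirtflow.kinetics import CalibrationCurve, ProgressCurve

__all__ = [
    "KineticTruth",
    "CellFieldTruth",
    "CellField",
    "FrapTruth",
    "ExpressionTruth",
    "RegulonTruth",
    "RegulonDB",
    "REFERENCE_TF_SPECS",
    "reference_regulon_truth",
    "REFERENCE_KINETICS",
    "CONDITIONS",
    "gen_calibration_curve",
    "gen_progress_curve",
    "gen_initial_rates",
    "gen_cell_field",
    "gen_frap_trace",
    "gen_expression_experiment",
    "tnfa_truth",
    "gen_regulon_db",
]

CONDITIONS: tuple[str, ...] = tuple("abcdefgh")
"""The eight experimental conditions: (a) unstimulated, (b) TNFα,
(c) enzyme transfected, (d) enzyme + TNFα, (e) dead mutant, (f) dead
mutant + TNFα, (g) empty vector, (h) empty vector + TNFα."""


class GenerationError(RuntimeError):
    """Raised when a generator cannot satisfy its geometric constraints."""


# --------------------------------------------------------------------------
# Kinetics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticTruth:
    """Ground truth for the deacetylase assay.

    ``kcat``, ``km_pep`` and ``km_nad`` are *apparent* constants referred
    to the co-substrate reference concentration ``nad_ref``: the NAD+
    saturation factor is normalised to 1 at ``nad_ref``, so a peptide
    titration at the reference NAD+ recovers exactly (kcat, km_pep) and an
    NAD+ titration recovers km_nad.
    """

    kcat: float = 0.001          # per minute (turnover at saturating peptide, reference NAD+)
    km_pep: float = 14.7         # µM, apparent K_m for the acetyl-peptide
    km_nad: float = 52.4         # µM, apparent K_m for NAD+
    enzyme_conc: float = 2.0     # µM
    calib_slope: float = 1000.0  # fluorescence units per µM product
    calib_intercept: float = 50.0  # background fluorescence units
    noise_sd: float = 0.0        # Gaussian signal noise, fluorescence units
    nad_ref: float = 500.0       # µM NAD+ at which kcat/km_pep are referred
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("kcat", "km_pep", "km_nad", "enzyme_conc", "nad_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def rate(self, s_pep: float | np.ndarray, s_nad: float | np.ndarray) -> float | np.ndarray:
        """Instantaneous product formation rate d[P]/dt in µM/min."""
        nad_factor = (s_nad / (self.km_nad + s_nad)) / (self.nad_ref / (self.km_nad + self.nad_ref))
        return self.kcat * self.enzyme_conc * (s_pep / (self.km_pep + s_pep)) * nad_factor


REFERENCE_KINETICS = KineticTruth()
"""Default truth preset matching the reported wild-type enzyme constants."""


def gen_calibration_curve(truth: KineticTruth,
                          products: Sequence[float] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0),
                          ) -> CalibrationCurve:
    """Noiseless calibration points signal = slope·product + intercept."""
    sig = tuple(truth.calib_slope * p + truth.calib_intercept for p in products)
    return CalibrationCurve(product=tuple(float(p) for p in products), signal=sig)


def _integrate_product(truth: KineticTruth, s_pep0: float, s_nad0: float,
                       t_end: float, step: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step midpoint integration of d[P]/dt with substrate depletion.

    Both substrates are consumed 1:1 with product.  At the assay's very low
    turnover, conversion per 0.05 min step is far below 0.1%, so the
    integration error is negligible against any measurement noise.
    """
    n = int(math.ceil(t_end / step)) + 1
    t = np.linspace(0.0, step * (n - 1), n)
    p = np.zeros(n)
    for i in range(1, n):
        pep = max(s_pep0 - p[i - 1], 0.0)
        nad = max(s_nad0 - p[i - 1], 0.0)
        k1 = truth.rate(pep, nad) if pep > 0 and nad > 0 else 0.0
        p_mid = p[i - 1] + 0.5 * step * k1
        pep_m = max(s_pep0 - p_mid, 0.0)
        nad_m = max(s_nad0 - p_mid, 0.0)
        k2 = truth.rate(pep_m, nad_m) if pep_m > 0 and nad_m > 0 else 0.0
        p[i] = p[i - 1] + step * k2
    return t, p


def gen_progress_curve(truth: KineticTruth, s_pep: float, s_nad: float,
                       timepoints: Sequence[float]) -> ProgressCurve:
    """Simulate one raw-fluorescence progress curve.

    Product formation is integrated with substrate depletion, converted to
    fluorescence through the truth's linear calibration, and Gaussian noise
    of sd ``truth.noise_sd`` (fluorescence units) is added per point.
    """
    tp = np.asarray(timepoints, dtype=float)
    if tp.ndim != 1 or tp.size < 2:
        raise ValueError("timepoints must be a 1-D sequence of at least 2 values")
    if tp[0] != 0.0 or np.any(np.diff(tp) <= 0):
        raise ValueError("timepoints must start at 0 and be strictly increasing")
    if s_pep <= 0 or s_nad <= 0:
        raise ValueError("substrate concentrations must be positive")
    t_grid, p_grid = _integrate_product(truth, s_pep, s_nad, float(tp[-1]))
    product = np.interp(tp, t_grid, p_grid)
    signal = truth.calib_slope * product + truth.calib_intercept
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        signal = signal + rng.normal(0.0, truth.noise_sd, size=signal.shape)
    return ProgressCurve(times=tp, signals=signal, enzyme_conc=truth.enzyme_conc,
                         s_pep=s_pep, s_nad=s_nad, converted=False, truth=truth)


def gen_initial_rates(truth: KineticTruth, vary: str, top: float,
                      n_dilutions: int = 8, rel_noise: float = 0.0,
                      fixed_pep: float = 10.0, fixed_nad: float | None = None,
                      ) -> list[tuple[float, float]]:
    """Initial velocities over a two-fold dilution series of one substrate.

    ``vary`` is ``"pep"`` or ``"nad"``; the series starts at ``top`` µM.
    Rates come from the closed-form rate law at t=0 with multiplicative
    Gaussian noise of fractional sd ``rel_noise`` — the measured-rate
    shortcut for titration experiments whose per-curve conversion is far
    below the initial-velocity limit.
    """
    if vary not in ("pep", "nad"):
        raise ValueError("vary must be 'pep' or 'nad'")
    if fixed_nad is None:
        fixed_nad = truth.nad_ref
    conc = top / (2.0 ** np.arange(n_dilutions))
    rng = np.random.default_rng(truth.seed)
    out = []
    for s in conc:
        if vary == "pep":
            v = truth.rate(s, fixed_nad)
        else:
            v = truth.rate(fixed_pep, s)
        if rel_noise > 0:
            v = v * (1.0 + rng.normal(0.0, rel_noise))
        out.append((float(s), float(v)))
    return out


# --------------------------------------------------------------------------
# Imaging: two-channel cell fields
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CellFieldTruth:
    """Ground truth for an idealised two-channel micrograph.

    Cells are modelled as a disk nucleus surrounded by an annular
    cytoplasm: the stain channel carries ``true_ratio × cyt_mean`` inside
    nuclei, ``cyt_mean`` in the annulus and ``background_mean`` elsewhere.
    Note the channels are stored 8-bit, so the measured ratio equals
    ``true_ratio`` exactly only when ``true_ratio·cyt_mean`` is integral.
    """

    n_cells: int = 100
    true_ratio: float = 2.0
    nucleus_radius_px: int = 10
    ring_width_px: int = 5
    cyt_mean: float = 100.0
    background_mean: float = 10.0
    noise_sd: float = 0.0
    image_size: int = 512
    seed: int = 0
    nuclear_fg: float = 200.0   # nuclear-stain disk intensity
    nuclear_bg: float = 5.0     # nuclear-stain background

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if not (0 < self.background_mean < self.cyt_mean):
            raise ValueError("need 0 < background_mean < cyt_mean")
        if self.true_ratio <= 0:
            raise ValueError("true_ratio must be positive")
        if self.true_ratio * self.cyt_mean > 255:
            raise ValueError("nuclear stain intensity exceeds the 8-bit range")


@dataclass
class CellField:
    """Generated image pair plus the per-cell truth records."""

    nuclear_channel: np.ndarray  # uint8
    stain_channel: np.ndarray  # uint8
    centers: list[tuple[int, int]]
    truth: CellFieldTruth


def _disk_mask(shape: tuple[int, int], center: tuple[int, int], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def gen_cell_field(truth: CellFieldTruth, max_tries: int = 20000) -> CellField:
    """Place non-overlapping disk-nucleus cells and paint both channels.

    Nuclei are placed by rejection sampling with a minimum centre distance
    that keeps each cell's annulus free of any other cell's nucleus, and
    with a border margin that keeps every annulus fully inside the image.
    """
    rng = np.random.default_rng(truth.seed)
    size = truth.image_size
    r = truth.nucleus_radius_px
    ring = truth.ring_width_px
    margin = r + ring + 2
    min_dist = 2 * r + ring + 3
    if truth.n_cells > 0 and size - 2 * margin <= 0:
        raise GenerationError("geometry does not fit the image")

    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < truth.n_cells:
        if tries >= max_tries:
            raise GenerationError(
                f"placed only {len(centers)}/{truth.n_cells} cells after {max_tries} tries"
            )
        tries += 1
        y = int(rng.integers(margin, size - margin))
        x = int(rng.integers(margin, size - margin))
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_dist ** 2 for cy, cx in centers):
            centers.append((y, x))

    shape = (size, size)
    nuclear = np.full(shape, truth.nuclear_bg, dtype=float)
    stain = np.full(shape, truth.background_mean, dtype=float)
    nuc_value = truth.true_ratio * truth.cyt_mean
    for c in centers:
        ann = _disk_mask(shape, c, r + ring) & ~_disk_mask(shape, c, r)
        stain[ann] = truth.cyt_mean
    for c in centers:
        nuc = _disk_mask(shape, c, r)
        nuclear[nuc] = truth.nuclear_fg
        stain[nuc] = nuc_value
    if truth.noise_sd > 0:
        nuclear = nuclear + rng.normal(0.0, truth.noise_sd, shape)
        stain = stain + rng.normal(0.0, truth.noise_sd, shape)
    nuclear8 = np.clip(np.round(nuclear), 0, 255).astype(np.uint8)
    stain8 = np.clip(np.round(stain), 0, 255).astype(np.uint8)
    return CellField(nuclear_channel=nuclear8, stain_channel=stain8,
                     centers=centers, truth=truth)


# --------------------------------------------------------------------------
# FRAP traces
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FrapTruth:
    """Ground truth for a single-exponential photobleaching recovery.

    Pre-bleach intensity is 1; the first post-bleach level is
    F0 = 1 − bleach_depth and the plateau is
    Finf = 1 − immobile_fraction·bleach_depth.
    """

    tau_s: float = 2.0
    immobile_fraction: float = 0.1
    bleach_depth: float = 0.6
    frame_interval_s: float = 0.27
    n_pre: int = 2
    n_bleach: int = 2
    n_recovery: int = 111  # ~30 s of recovery at 0.27 s per frame
    noise_sd: float = 0.0  # fraction of pre-bleach intensity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if not (0 <= self.immobile_fraction <= 1):
            raise ValueError("immobile_fraction must be in [0, 1]")
        if not (0 < self.bleach_depth <= 1):
            raise ValueError("bleach_depth must be in (0, 1]")
        if self.n_recovery < 5:
            raise ValueError("need at least 5 recovery frames")
        if self.n_pre < 1:
            raise ValueError("need at least 1 pre-bleach frame")

    @property
    def f0(self) -> float:
        return 1.0 - self.bleach_depth

    @property
    def finf(self) -> float:
        return 1.0 - self.immobile_fraction * self.bleach_depth


def gen_frap_trace(truth: FrapTruth) -> FrapTrace:
    """Simulate pre-bleach, bleach and recovery frames at fixed interval.

    Recovery follows F(t) = F0 + (Finf − F0)(1 − exp(−t/τ)) with t measured
    from the first post-bleach frame; bleach frames are recorded at F0.
    """
    dt = truth.frame_interval_s
    n_total = truth.n_pre + truth.n_bleach + truth.n_recovery
    times = np.arange(n_total) * dt
    intensities = np.empty(n_total)
    intensities[: truth.n_pre] = 1.0
    intensities[truth.n_pre: truth.n_pre + truth.n_bleach] = truth.f0
    t_rec = np.arange(truth.n_recovery) * dt
    intensities[truth.n_pre + truth.n_bleach:] = truth.f0 + (truth.finf - truth.f0) * (
        1.0 - np.exp(-t_rec / truth.tau_s)
    )
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        intensities = intensities + rng.normal(0.0, truth.noise_sd, n_total)
    return FrapTrace(times_s=times, intensities=intensities,
                     n_pre=truth.n_pre, n_bleach=truth.n_bleach, truth=truth)


# --------------------------------------------------------------------------
# Expression experiments
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionTruth:
    """Planted-effect design for a triplicate 8-condition log2 matrix.

    ``effects`` maps a condition letter to {probe index: log2 shift};
    probes absent from a condition's map sit at their baseline there.
    Per-probe baselines are drawn once (N(baseline_mean, 1)) and shared
    across all samples, so condition contrasts isolate the planted shifts.
    """

    n_probes: int = 2000
    n_reps: int = 3
    effects: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    replicate_sd: float = 0.25
    baseline_mean: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1 or self.n_reps < 2:
            raise ValueError("need n_probes >= 1 and n_reps >= 2")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be non-negative")
        for cond, eff in self.effects.items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition label {cond!r}")
            for probe in eff:
                if not (0 <= probe < self.n_probes):
                    raise ValueError(f"planted probe {probe} outside [0, {self.n_probes})")

    def planted_up(self, test: str, ref: str) -> set[int]:
        """Probes whose planted test−reference shift is positive."""
        return {p for p, d in self._deltas(test, ref).items() if d > 0}

    def planted_down(self, test: str, ref: str) -> set[int]:
        return {p for p, d in self._deltas(test, ref).items() if d < 0}

    def _deltas(self, test: str, ref: str) -> dict[int, float]:
        te = self.effects.get(test, {})
        re_ = self.effects.get(ref, {})
        return {p: te.get(p, 0.0) - re_.get(p, 0.0) for p in set(te) | set(re_)}


def probe_id(i: int) -> str:
    return f"P{i:06d}"


def gen_expression_experiment(truth: ExpressionTruth) -> pd.DataFrame:
    """Generate the log2 intensity matrix (probes × 8 conditions × reps)."""
    rng = np.random.default_rng(truth.seed)
    base = rng.normal(truth.baseline_mean, 1.0, truth.n_probes)
    cols = {}
    for cond in CONDITIONS:
        shift = np.zeros(truth.n_probes)
        for probe, eff in truth.effects.get(cond, {}).items():
            shift[probe] = eff
        for rep in range(1, truth.n_reps + 1):
            noise = rng.normal(0.0, truth.replicate_sd, truth.n_probes) if truth.replicate_sd > 0 else 0.0
            cols[f"{cond}_{rep}"] = base + shift + noise
    return pd.DataFrame(cols, index=[probe_id(i) for i in range(truth.n_probes)])


def tnfa_truth(n_probes: int = 2000, n_up: int = 153, n_down: int = 45,
               effect_up: float = 1.5, effect_down: float = -1.5,
               replicate_sd: float = 0.25, seed: int = 0) -> ExpressionTruth:
    """Preset emulating a TNFα response shared by two stimulation contrasts.

    The same blocks of up- and down-shifted probes are planted in the two
    stimulated conditions (b: stimulation alone; h: empty vector +
    stimulation), so the direction-consistent overlap of contrasts b-vs-a
    and h-vs-g recovers exactly these blocks.
    """
    if n_up + n_down > n_probes:
        raise ValueError("planted blocks exceed n_probes")
    up = {i: effect_up for i in range(n_up)}
    down = {i: effect_down for i in range(n_up, n_up + n_down)}
    stim = {**up, **down}
    return ExpressionTruth(n_probes=n_probes, effects={"b": stim, "h": dict(stim)},
                           replicate_sd=replicate_sd, seed=seed)


# --------------------------------------------------------------------------
# Regulon databases
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RegulonTruth:
    """Specification of a synthetic interaction database and query set.

    ``tf_specs`` is a list of (name, regulon size R, planted overlap k with
    the query) in a universe of ``universe_n`` genes against a query of
    ``query_size`` genes.
    """

    universe_n: int
    tf_specs: tuple[tuple[str, int, int], ...]
    query_size: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.query_size <= self.universe_n):
            raise ValueError("query_size must be in [1, universe_n]")
        for name, r, k in self.tf_specs:
            if not (1 <= r <= self.universe_n):
                raise ValueError(f"{name}: R must be in [1, N]")
            if not (0 <= k <= min(r, self.query_size)):
                raise ValueError(f"{name}: need 0 <= k <= min(R, n)")
            if r - k > self.universe_n - self.query_size:
                raise ValueError(f"{name}: regulon cannot avoid the query enough for k={k}")


@dataclass
class RegulonDB:
    """A named family of regulator target sets over a fixed gene universe."""

    universe_n: int
    regulons: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, genes in self.regulons.items():
            if len(genes) < 1:
                raise ValueError(f"regulon {name!r} is empty")


REFERENCE_TF_SPECS: tuple[tuple[str, int, int], ...] = (
    ("RelA", 451, 47),
    ("c-Rel", 330, 37),
    ("NF-kB1", 200, 29),
    ("SP1", 2410, 57),
    ("RelB", 41, 10),
    ("c-Jun", 475, 22),
    ("CREB1", 1024, 32),
    ("EGR1", 587, 24),
    ("ETS1", 462, 19),
    ("STAT3", 373, 17),
    ("NF-kB p65/p65", 24, 6),
    ("NF-kB2", 44, 7),
)
"""(name, regulon size R, overlap k) for the NF-kB-centred worked example:
twelve regulators of a 200-gene stimulus-response profile queried against a
22651-gene interaction database."""


def reference_regulon_truth(seed: int = 0) -> RegulonTruth:
    """Worked-example database design: N=22651, query of 200 genes, 12 TFs."""
    return RegulonTruth(universe_n=22651, tf_specs=REFERENCE_TF_SPECS,
                        query_size=200, seed=seed)


def gene_id(i: int) -> str:
    return f"G{i:06d}"


def gen_regulon_db(truth: RegulonTruth) -> tuple[RegulonDB, frozenset[str]]:
    """Build a universe, a query set and regulons with exact planted overlaps."""
    rng = np.random.default_rng(truth.seed)
    universe = np.array([gene_id(i) for i in range(truth.universe_n)])
    perm = rng.permutation(truth.universe_n)
    query_idx = perm[: truth.query_size]
    rest_idx = perm[truth.query_size:]
    query = frozenset(universe[query_idx])
    regulons: dict[str, frozenset[str]] = {}
    for name, r, k in truth.tf_specs:
        if name in regulons:
            raise ValueError(f"duplicate TF name {name!r}")
        inside = rng.choice(query_idx, size=k, replace=False) if k else np.array([], dtype=int)
        outside = rng.choice(rest_idx, size=r - k, replace=False) if r - k else np.array([], dtype=int)
        regulons[name] = frozenset(universe[np.concatenate([inside, outside]).astype(int)])
    return RegulonDB(universe_n=truth.universe_n, regulons=regulons), query
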