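"""Stochastic two-state barcoded clonal population simulator.

Simulates an AML population in which every cell carries a heritable DNA
barcode (clone label) and occupies one of two reporter-defined signalling
states:

* ``H`` — mTORC1-high (probe degraded, mVenus-low), more actively cycling,
  preferentially killed by cell-cycle-specific chemotherapy;
* ``L`` — mTORC1-low (probe stable, mVenus-high).

Per-cell events are birth, death, chemotherapy kill (active only inside the
treatment window) and H<->L state transitions.  The L->H transition rate is
modulated by a nutrient level that decays with total marrow burden,
``nutrient = K / (K + burden)``, which reproduces the observed suppression of
mTORC1 activity as disease burden grows.

Two mechanistic templates are expressible:

* ``selection`` — zero state transitions and state-differential kill: every
  clone is frozen in its founder state, and treatment enriches one state by
  differential survival;
* ``induction`` — symmetric, nutrient-coupled transitions: surviving cells
  re-equilibrate between states regardless of ancestry.

Populations of 1e5–1e9 cells are advanced with a discrete-time tau-leaping
integrator (default ``dt`` = 0.1 day).  An exact Gillespie stochastic
simulation algorithm is provided for small populations (<= 1e4 cells) as a
cross-validation oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "RateSet",
    "MechanismSpec",
    "CloneTable",
    "ChemoSchedule",
    "ExperimentDesign",
    "Trajectory",
    "StepSizeError",
    "seed_library",
    "make_mechanism_rates",
    "nutrient_level",
    "step",
    "step_gillespie",
    "run_experiment",
    "sort_sample",
]


class StepSizeError(ValueError):
    """Raised when rate*dt is too large for a tau-leap step to be valid."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateSet:
    """Per-day event rates for the two-state birth-death-transition process.

    Parameters
    ----------
    birth_H, birth_L : float
        Division rates per cell per day.  ``birth_H >= birth_L`` emulates the
        faster cycling of mTORC1-high cells.
    death_H, death_L : float
        Baseline (treatment-independent) death rates per day.
    trans_HL, trans_LH : float
        Baseline state-transition rates per day (H->L and L->H).  The
        effective L->H rate is ``trans_LH * (1 + nutrient_coupling * nutrient)``.
    kill_H, kill_L : float
        Additional death hazards applied only while chemotherapy is active.
    nutrient_coupling : float
        Dimensionless gain coupling the L->H transition to nutrient level.
    capacity_K : float
        Total burden at which nutrient availability is half-maximal.
    """

    birth_H: float
    birth_L: float
    death_H: float
    death_L: float
    trans_HL: float
    trans_LH: float
    kill_H: float
    kill_L: float
    nutrient_coupling: float = 0.0
    capacity_K: float = 2e8

    def __post_init__(self) -> None:
        for name in (
            "birth_H", "birth_L", "death_H", "death_L",
            "trans_HL", "trans_LH", "kill_H", "kill_L", "nutrient_coupling",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0, got {getattr(self, name)}")
        if self.capacity_K <= 0:
            raise ValueError(f"capacity_K must be > 0, got {self.capacity_K}")


@dataclass(frozen=True)
class MechanismSpec:
    """Scenario switch selecting the mechanistic rate template.

    ``selection`` freezes state transitions at zero with state-differential
    kill; ``induction`` uses symmetric nonzero transitions with nutrient
    coupling; ``mixed`` interpolates the two templates with ``mixing_weight``
    as the weight on the induction template.
    """

    mechanism: Literal["selection", "induction", "mixed"]
    mixing_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.mechanism not in ("selection", "induction", "mixed"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not 0.0 <= self.mixing_weight <= 1.0:
            raise ValueError(f"mixing_weight must be in [0, 1], got {self.mixing_weight}")


@dataclass
class CloneTable:
    """Per-clone cell counts split by mTORC1 state.

    ``clone_id``, ``n_H`` and ``n_L`` are parallel integer arrays; clone ids
    are unique.  ``meta`` carries provenance counters (e.g. the number of
    multi-integration founders).
    """

    clone_id: np.ndarray
    n_H: np.ndarray
    n_L: np.ndarray
    time_day: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.clone_id = np.asarray(self.clone_id, dtype=np.int64)
        self.n_H = np.asarray(self.n_H, dtype=np.int64)
        self.n_L = np.asarray(self.n_L, dtype=np.int64)
        if not (len(self.clone_id) == len(self.n_H) == len(self.n_L)):
            raise ValueError("clone_id, n_H, n_L must have equal length")
        if len(np.unique(self.clone_id)) != len(self.clone_id):
            raise ValueError("clone ids must be unique")
        if (self.n_H < 0).any() or (self.n_L < 0).any():
            raise ValueError("cell counts must be nonnegative")

    @property
    def n_clones(self) -> int:
        return len(self.clone_id)

    @property
    def total_burden(self) -> int:
        return int(self.n_H.sum() + self.n_L.sum())

    @property
    def total_H(self) -> int:
        return int(self.n_H.sum())

    @property
    def total_L(self) -> int:
        return int(self.n_L.sum())

    def copy(self, time_day: float | None = None) -> "CloneTable":
        return CloneTable(
            self.clone_id.copy(), self.n_H.copy(), self.n_L.copy(),
            self.time_day if time_day is None else time_day, dict(self.meta),
        )

    def drop_extinct(self) -> "CloneTable":
        """Return a table restricted to clones with at least one live cell."""
        keep = (self.n_H + self.n_L) > 0
        return CloneTable(self.clone_id[keep], self.n_H[keep], self.n_L[keep],
                          self.time_day, dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"clone_id": self.clone_id, "n_H": self.n_H, "n_L": self.n_L}
        )


@dataclass(frozen=True)
class ChemoSchedule:
    """Chemotherapy timing on the treatment clock.

    Mirrors the clinical-style regimen: cytarabine for ``arac_days`` with
    doxorubicin given concurrently for the first ``dox_days``.  Kill hazards
    are constant within ``[start_day, start_day + arac_days)``; no
    pharmacokinetics are modelled.
    """

    start_day: float = 0.0
    arac_days: int = 5
    dox_days: int = 3

    def __post_init__(self) -> None:
        if not (self.arac_days >= self.dox_days >= 0):
            raise ValueError("require arac_days >= dox_days >= 0")

    def active(self, day: float) -> bool:
        return self.start_day <= day < self.start_day + self.arac_days


@dataclass(frozen=True)
class ExperimentDesign:
    """In-silico analogue of the barcoding transplantation experiment.

    Defaults follow the published workflow: two million cells exposed to the
    barcode library at <10% multiplicity of infection (~0.2 million barcoded
    founders), one million cells transplanted per animal, treatment started
    21 days after transplant, bone marrow sampled on treatment days 0/5/7/14
    with 400,000 cells sorted per mTORC1 gate.
    """

    n_exposed_cells: int = 2_000_000
    infection_prob: float = 0.1
    library_size: int = 10_000_000
    n_transplanted: int = 1_000_000
    sampling_days: tuple[float, ...] = (0.0, 5.0, 7.0, 14.0)
    n_sorted_per_gate: int = 400_000
    initial_high_fraction: float = 0.5
    growth_days: float = 21.0
    dt: float = 0.1
    dt_growth: float = 0.25    # coarser leap for the no-treatment engraftment phase
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.infection_prob <= 1.0:
            raise ValueError("infection_prob must be in [0, 1]")
        if self.n_exposed_cells < 0 or self.library_size < 1:
            raise ValueError("invalid exposure/library parameters")
        if list(self.sampling_days) != sorted(self.sampling_days):
            raise ValueError("sampling_days must be sorted ascending")
        if any(d < 0 for d in self.sampling_days):
            raise ValueError("sampling_days are on the treatment clock (>= 0)")
        if not 0.0 <= self.initial_high_fraction <= 1.0:
            raise ValueError("initial_high_fraction must be in [0, 1]")
        if self.dt <= 0 or self.dt_growth <= 0:
            raise ValueError("step sizes must be positive")


@dataclass
class Trajectory:
    """Recorded output of one in-silico experiment.

    ``times``/``burden``/``nutrient`` trace every integrator step (treatment
    clock; negative times are the engraftment phase).  Full clone tables are
    snapshotted only at sampling days, alongside the gate-sorted barcode
    count vectors (one pandas Series per (day, gate), indexed by clone id).
    """

    times: np.ndarray
    burden: np.ndarray
    nutrient: np.ndarray
    snapshots: dict[float, CloneTable]
    sorted_counts: dict[tuple[float, str], pd.Series]
    truncated: dict[tuple[float, str], bool]
    extinct: bool = False
    design: ExperimentDesign | None = None

    def burden_at(self, day: float) -> int:
        idx = int(np.argmin(np.abs(self.times - day)))
        return int(self.burden[idx])


# ---------------------------------------------------------------------------
# Library seeding
# ---------------------------------------------------------------------------


def seed_library(
    n_exposed_cells: int,
    infection_prob: float,
    library_size: int,
    initial_high_fraction: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> CloneTable:
    """Expose cells to a lentiviral barcode library and return the founders.

    Each exposed cell acquires ``k ~ Poisson(-ln(1 - infection_prob))``
    integrations, so that the fraction of cells with k >= 1 equals
    ``infection_prob`` exactly.  Cells with k >= 1 become barcoded founders;
    multi-integration cells (k >= 2) are tracked under a single barcode and
    their number reported in ``meta['n_multi_integration']``, mirroring
    standard practice at low multiplicity of infection where they are rare.
    Each founder draws its barcode uniformly from the library; founders that
    collide on a barcode are merged into one clone and counted in
    ``meta['n_barcode_collisions']``.

    Founder states are assigned H with probability ``initial_high_fraction``.
    """
    if n_exposed_cells < 0:
        raise ValueError("n_exposed_cells must be >= 0")
    if not 0.0 <= infection_prob <= 1.0:
        raise ValueError("infection_prob must be in [0, 1]")
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if infection_prob == 0.0 or n_exposed_cells == 0:
        empty = np.empty(0, dtype=np.int64)
        return CloneTable(empty, empty.copy(), empty.copy(), 0.0,
                          {"n_founders": 0, "n_multi_integration": 0,
                           "n_barcode_collisions": 0})

    lam = -np.log1p(-infection_prob) if infection_prob < 1.0 else np.inf
    if np.isinf(lam):
        k = np.ones(n_exposed_cells, dtype=np.int64)
    else:
        k = rng.poisson(lam, size=n_exposed_cells)
    founders = int((k >= 1).sum())
    n_multi = int((k >= 2).sum())

    states_high = rng.random(founders) < initial_high_fraction
    if founders <= library_size:
        # distinct barcode per founder (rejection redraw of duplicates);
        # high-complexity libraries make collisions negligible in practice
        # and uniqueness keeps clone identity exact
        barcodes = rng.integers(0, library_size, size=founders, dtype=np.int64)
        while True:
            uniq, first = np.unique(barcodes, return_index=True)
            if len(uniq) == founders:
                break
            dup = np.ones(founders, dtype=bool)
            dup[first] = False
            barcodes[dup] = rng.integers(0, library_size, size=int(dup.sum()),
                                         dtype=np.int64)
        n_collisions = 0
    else:
        warnings.warn(
            f"library_size={library_size} smaller than founder demand "
            f"({founders}); barcode collisions will merge clones", stacklevel=2)
        barcodes = rng.integers(0, library_size, size=founders, dtype=np.int64)

    clone_id, inverse = np.unique(barcodes, return_inverse=True)
    n_collisions = founders - len(clone_id)
    n_H = np.bincount(inverse, weights=states_high).astype(np.int64)
    n_L = np.bincount(inverse, weights=~states_high).astype(np.int64)

    return CloneTable(clone_id, n_H, n_L, 0.0,
                      {"n_founders": founders, "n_multi_integration": n_multi,
                       "n_barcode_collisions": int(n_collisions)})


# ---------------------------------------------------------------------------
# Mechanism templates
# ---------------------------------------------------------------------------


def make_mechanism_rates(spec: MechanismSpec, base: RateSet) -> RateSet:
    """Instantiate the rate template for a mechanistic scenario.

    ``base`` is the induction-side parameterisation (transitions, coupling,
    per-state kill).  The templates are:

    * selection — transitions and nutrient coupling forced to exactly zero;
      kill rates oriented so that ``kill_L > kill_H`` (mTORC1-low cells are
      preferentially removed in vivo, so the survivor pool reads "high");
    * induction — transitions symmetrised to the mean of the base rates
      (must be nonzero) with positive nutrient coupling; kill per state as
      configured;
    * mixed — elementwise convex combination, ``mixing_weight`` on the
      induction template.
    """
    trans_mean = 0.5 * (base.trans_HL + base.trans_LH)
    kill_lo, kill_hi = sorted((base.kill_H, base.kill_L))
    selection = replace(base, trans_HL=0.0, trans_LH=0.0, nutrient_coupling=0.0,
                        kill_H=kill_lo, kill_L=kill_hi)
    if spec.mechanism == "selection":
        return selection

    if trans_mean <= 0.0:
        raise ValueError("induction template requires nonzero base transition rates")
    if base.nutrient_coupling <= 0.0:
        raise ValueError("induction template requires nutrient_coupling > 0")
    induction = replace(base, trans_HL=trans_mean, trans_LH=trans_mean)
    if spec.mechanism == "induction":
        return induction

    w = spec.mixing_weight
    mix = {
        f: (1.0 - w) * getattr(selection, f) + w * getattr(induction, f)
        for f in ("birth_H", "birth_L", "death_H", "death_L", "trans_HL",
                  "trans_LH", "kill_H", "kill_L", "nutrient_coupling", "capacity_K")
    }
    return RateSet(**mix)


def nutrient_level(total_burden: float, capacity_K: float) -> float:
    """Nutrient availability as a saturating function of marrow burden.

    Returns ``K / (K + burden)``: 1 for an empty marrow, 1/2 at burden K,
    monotone decreasing.  This encodes the observed negative correlation
    between AML burden and mTORC1 activity without independent nutrient
    kinetics.
    """
    if capacity_K <= 0:
        raise ValueError("capacity_K must be > 0")
    if total_burden < 0:
        raise ValueError("total_burden must be >= 0")
    return capacity_K / (capacity_K + total_burden)


# ---------------------------------------------------------------------------
# Tau-leap integrator
# ---------------------------------------------------------------------------

_NORMAL_APPROX_VAR = 25.0   # binomial draws above this variance use a
                            # rounded, range-clipped normal (exact mean and
                            # variance; skewness < 0.2 at this threshold)


def _fast_table(clone_id, n_H, n_L, time_day, meta) -> CloneTable:
    """CloneTable constructor bypassing validation (hot loop use only)."""
    t = object.__new__(CloneTable)
    t.clone_id, t.n_H, t.n_L, t.time_day, t.meta = clone_id, n_H, n_L, time_day, meta
    return t


def _binomial(rng: np.random.Generator, n: np.ndarray, p: float) -> np.ndarray:
    """Vectorised per-clone event-count draw for one tau-leap channel.

    Exact binomial, except (a) above ``_NORMAL_APPROX_VAR`` a rounded,
    range-clipped normal is used, and (b) for small success probability
    (p <= 0.1) a count-clipped Poisson draw — the classic Poisson tau-leap —
    replaces the binomial.  Means and variances match the binomial to O(p);
    both shortcuts are standard for leap methods at large population sizes.
    """
    if p <= 0.0:
        return np.zeros_like(n)
    if p >= 1.0:
        return n.copy()
    var = n * (p * (1.0 - p))
    big = var > _NORMAL_APPROX_VAR
    out = np.empty_like(n)
    nbig = int(big.sum())
    if nbig < len(n):
        small = ~big
        ns = n[small]
        if p <= 0.1:
            out[small] = np.minimum(rng.poisson(ns * p), ns)
        else:
            out[small] = rng.binomial(ns, p)
    if nbig:
        nb = n[big]
        draw = np.rint(rng.normal(nb * p, np.sqrt(var[big]))).astype(np.int64)
        out[big] = np.clip(draw, 0, nb)
    return out


def _poisson(rng: np.random.Generator, lam: np.ndarray) -> np.ndarray:
    """Vectorised Poisson with a rounded-normal branch for large means."""
    big = lam > _NORMAL_APPROX_VAR
    out = np.empty(len(lam), dtype=np.int64)
    nbig = int(big.sum())
    if nbig < len(lam):
        out[~big] = rng.poisson(lam[~big])
    if nbig:
        lb = lam[big]
        out[big] = np.maximum(np.rint(rng.normal(lb, np.sqrt(lb))).astype(np.int64), 0)
    return out


def _split_exact(rng: np.random.Generator, n: np.ndarray, hazards: list[float],
                 p_tot: float, total_rate: float) -> list[np.ndarray]:
    """Exact competing-risks removals: binomial total, conditional splits."""
    out: list[np.ndarray] = []
    remaining = rng.binomial(n, p_tot)
    rate_left = total_rate
    for h in hazards[:-1]:
        frac = h / rate_left if rate_left > 0 else 0.0
        take = rng.binomial(remaining, frac)
        out.append(take)
        remaining = remaining - take
        rate_left -= h
    out.append(remaining)
    return out


def _split_removals(rng: np.random.Generator, n: np.ndarray,
                    hazards: list[float], dt: float) -> list[np.ndarray]:
    """Competing-risks removal draw for one state across all clones.

    Cause-specific removals are drawn as independent Poisson channels with
    intensities ``n * (h_c / out) * (1 - exp(-out dt))`` — the exact
    competing-risks means.  Wherever the channel totals would exceed the
    available cells (possible only at small counts), those clones are
    redrawn with the exact scheme: a binomial total split by conditional
    binomials.
    """
    total_rate = float(sum(hazards))
    if total_rate == 0.0:
        return [np.zeros_like(n) for _ in hazards]
    p_tot = -np.expm1(-total_rate * dt)
    out = [
        _poisson(rng, n * ((h / total_rate) * p_tot)) if h > 0 else np.zeros_like(n)
        for h in hazards
    ]
    tot = out[0]
    for o in out[1:]:
        tot = tot + o
    over = tot > n
    if over.any():
        exact = _split_exact(rng, n[over], hazards, p_tot, total_rate)
        for o, e in zip(out, exact):
            o[over] = e
    return out


def step(
    clones: CloneTable,
    rates: RateSet,
    chemo_active: bool,
    nutrient: float,
    dt: float,
    seed: int | np.random.Generator = 0,
) -> CloneTable:
    """Advance the population by one tau-leap of length ``dt`` days.

    Removals (death, chemotherapy kill, transition out) are drawn as
    competing binomial risks per clone and state with per-event probability
    ``1 - exp(-rate * dt)``.  Births are Poisson with survivor-adjusted
    intensity ``n * (e^(b dt) - 1) * e^(-out dt)``, which makes the one-step
    mean of the linear birth-death system exact at any step size (the pure
    birth-death mean is N0 * e^((b-d)t) to machine precision, not just to
    O(dt)).  The effective L->H rate is
    ``trans_LH * (1 + nutrient_coupling * nutrient)``.  Counts stay
    nonnegative integers and, with all rates zero, the input is returned
    unchanged.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    kH = rates.kill_H if chemo_active else 0.0
    kL = rates.kill_L if chemo_active else 0.0
    trans_LH_eff = rates.trans_LH * (1.0 + rates.nutrient_coupling * nutrient)

    out_H = rates.death_H + kH + rates.trans_HL
    out_L = rates.death_L + kL + trans_LH_eff
    # Guard tau-leap validity: total outflow probability per step must stay
    # well below certainty or the leap approximation degrades.
    if max(out_H, out_L, rates.birth_H, rates.birth_L) * dt > 1.0:
        raise StepSizeError(
            f"rate*dt exceeds 1 (max {max(out_H, out_L, rates.birth_H, rates.birth_L) * dt:.3f}); "
            "reduce dt")

    n_H, n_L = clones.n_H, clones.n_L

    g_H = np.expm1(rates.birth_H * dt) * np.exp(-out_H * dt)
    g_L = np.expm1(rates.birth_L * dt) * np.exp(-out_L * dt)
    births_H = _poisson(rng, n_H * g_H) if rates.birth_H > 0 else 0
    births_L = _poisson(rng, n_L * g_L) if rates.birth_L > 0 else 0

    death_H_n, kill_H_n, h_to_l = _split_removals(rng, n_H, [rates.death_H, kH, rates.trans_HL], dt)
    death_L_n, kill_L_n, l_to_h = _split_removals(rng, n_L, [rates.death_L, kL, trans_LH_eff], dt)

    new_H = n_H + births_H - death_H_n - kill_H_n - h_to_l + l_to_h
    new_L = n_L + births_L - death_L_n - kill_L_n - l_to_h + h_to_l

    return _fast_table(clones.clone_id, new_H, new_L, clones.time_day + dt,
                       clones.meta)


def step_gillespie(
    clones: CloneTable,
    rates: RateSet,
    chemo_active: bool,
    nutrient: float,
    duration: float,
    seed: int | np.random.Generator = 0,
    max_cells: int = 10_000,
) -> CloneTable:
    """Exact stochastic simulation over ``duration`` days (small populations).

    Event-by-event Gillespie algorithm used as a cross-validation oracle for
    the tau-leap integrator; refuses populations above ``max_cells``.
    Nutrient is held fixed at the supplied value for the interval.
    """
    if clones.total_burden > max_cells:
        raise ValueError(f"Gillespie oracle limited to {max_cells} cells")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    kH = rates.kill_H if chemo_active else 0.0
    kL = rates.kill_L if chemo_active else 0.0
    trans_LH_eff = rates.trans_LH * (1.0 + rates.nutrient_coupling * nutrient)
    n_H = clones.n_H.astype(np.float64).copy()
    n_L = clones.n_L.astype(np.float64).copy()

    # per-cell hazards: (state, delta_H, delta_L)
    chan = [
        ("H", rates.birth_H, +1, 0), ("L", rates.birth_L, 0, +1),
        ("H", rates.death_H + kH, -1, 0), ("L", rates.death_L + kL, 0, -1),
        ("H", rates.trans_HL, -1, +1), ("L", trans_LH_eff, +1, -1),
    ]
    t = 0.0
    while True:
        prop = np.zeros((len(chan), len(n_H)))
        for i, (st, rate, _, _) in enumerate(chan):
            prop[i] = rate * (n_H if st == "H" else n_L)
        total = prop.sum()
        if total == 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= duration:
            break
        flat = prop.ravel()
        idx = rng.choice(len(flat), p=flat / total)
        ci, clone = divmod(idx, len(n_H))
        n_H[clone] += chan[ci][2]
        n_L[clone] += chan[ci][3]
    return CloneTable(clones.clone_id, n_H.astype(np.int64), n_L.astype(np.int64),
                      clones.time_day + duration, dict(clones.meta))


# ---------------------------------------------------------------------------
# Sorting and the full in-silico experiment
# ---------------------------------------------------------------------------


def sort_sample(
    clones: CloneTable,
    gate_state: str,
    n_cells: int,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.Series, bool]:
    """Sort ``n_cells`` from one mTORC1 gate without replacement.

    Draws a multivariate hypergeometric sample across clones from the cells
    of the requested state.  If fewer cells are available than requested all
    are returned and the truncation flag is set.  Returns (counts indexed by
    clone id, truncated).
    """
    if gate_state not in ("H", "L"):
        raise ValueError("gate_state must be 'H' or 'L'")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    pool = clones.n_H if gate_state == "H" else clones.n_L
    available = int(pool.sum())
    truncated = n_cells > available
    n_draw = min(n_cells, available)
    if n_draw == 0:
        counts = np.zeros(clones.n_clones, dtype=np.int64)
    elif n_draw == available:
        counts = pool.copy()
    else:
        counts = _multivariate_hypergeometric(rng, pool, n_draw)
    return pd.Series(counts, index=clones.clone_id, name=f"gate_{gate_state}"), truncated


def _multivariate_hypergeometric(rng: np.random.Generator, colors: np.ndarray,
                                 nsample: int) -> np.ndarray:
    """Multivariate hypergeometric draw valid for populations beyond 1e9.

    numpy's 'marginals' method caps the population size; above the cap the
    draw falls back to the sequential conditional scheme over categories,
    using a range-clipped binomial for conditionals whose population exceeds
    the cap of the scalar hypergeometric generator (the finite-population
    variance correction is then below 1e-4 relative, since the sample is a
    vanishing fraction of the pool).
    """
    total = int(colors.sum())
    if total < 1_000_000_000:
        return rng.multivariate_hypergeometric(colors, nsample, method="marginals")
    cap = 1_000_000_000
    out = np.zeros(len(colors), dtype=np.int64)
    remaining, k = total, nsample
    for i, c in enumerate(colors):
        if k == 0:
            break
        c = int(c)
        if c == 0:
            continue
        if c >= remaining:
            x = k
        elif c < cap and remaining - c < cap:
            x = int(rng.hypergeometric(c, remaining - c, k))
        else:
            x = int(rng.binomial(k, c / remaining))
            x = max(k - (remaining - c), min(x, c, k))
        out[i] = x
        k -= x
        remaining -= c
    return out


def run_experiment(
    design: ExperimentDesign,
    spec: MechanismSpec | None,
    rates: RateSet,
    schedule: ChemoSchedule | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Run the full barcoding experiment in silico.

    Workflow: seed the barcode library, transplant ``n_transplanted`` cells
    (proportional multinomial expansion of the founder pool when more cells
    are transplanted than founders exist, preserving founder states), grow
    for ``design.growth_days`` days, then apply chemotherapy on the treatment
    clock per ``schedule`` and record the trajectory.  At each sampling day a
    clone-table snapshot is stored and 400,000-cell (default) sorts of each
    mTORC1 gate are emitted.

    Deterministic given (design, spec, rates, schedule, seed); ``seed``
    overrides ``design.seed`` when given.  ``spec=None`` uses ``rates``
    verbatim (no mechanism template applied), for calibration runs.
    """
    schedule = schedule or ChemoSchedule()
    master = np.random.SeedSequence(design.seed if seed is None else seed)
    rng_lib, rng_tx, rng_dyn, rng_sort = (np.random.default_rng(s) for s in master.spawn(4))

    mech_rates = make_mechanism_rates(spec, rates) if spec is not None else rates

    founders = seed_library(design.n_exposed_cells, design.infection_prob,
                            design.library_size, design.initial_high_fraction,
                            rng_lib)
    if founders.total_burden == 0:
        return Trajectory(np.array([0.0]), np.array([0]), np.array([1.0]),
                          {}, {}, {}, extinct=True, design=design)

    clones = _transplant(founders, design.n_transplanted, rng_tx)

    t0 = -float(design.growth_days)  # treatment clock
    t_end = float(max(design.sampling_days))
    grid = _time_grid(t0, t_end, design.dt, design.dt_growth,
                      schedule.start_day, schedule.start_day + schedule.arac_days,
                      design.sampling_days)
    n_steps = len(grid) - 1
    sampling = {float(d) for d in design.sampling_days}

    times = np.empty(n_steps + 1)
    burden = np.empty(n_steps + 1, dtype=np.int64)
    nutr = np.empty(n_steps + 1)
    snapshots: dict[float, CloneTable] = {}
    sorted_counts: dict[tuple[float, str], pd.Series] = {}
    truncated: dict[tuple[float, str], bool] = {}
    extinct = False
    first_sampling = min(sampling) if sampling else np.inf

    clones.time_day = grid[0]
    for i, t in enumerate(grid):
        b = clones.total_burden
        nu = nutrient_level(b, mech_rates.capacity_K)
        times[i], burden[i], nutr[i] = t, b, nu

        day_key = round(float(t), 6)
        if day_key in sampling:
            snap = clones.drop_extinct().copy(time_day=t)
            snapshots[day_key] = snap
            for gate in ("H", "L"):
                cnt, trunc = sort_sample(snap, gate, design.n_sorted_per_gate, rng_sort)
                sorted_counts[(day_key, gate)] = cnt[cnt > 0]
                truncated[(day_key, gate)] = trunc

        if b == 0 and t < first_sampling:
            extinct = True
        if i == n_steps:
            break
        dt_i = float(grid[i + 1] - t)
        clones = step(clones, mech_rates, schedule.active(t), nu, dt_i, rng_dyn)
        if i % 10 == 9:  # shed fully-extinct clones (exact: they cannot revive)
            alive = (clones.n_H + clones.n_L) > 0
            if int(alive.sum()) < 0.9 * clones.n_clones:
                clones = _fast_table(clones.clone_id[alive], clones.n_H[alive],
                                     clones.n_L[alive], clones.time_day, clones.meta)

    return Trajectory(times, burden, nutr, snapshots, sorted_counts, truncated,
                      extinct=extinct, design=design)


def _time_grid(t0: float, t_end: float, dt_fine: float, dt_coarse: float,
               fine_lo: float, fine_hi: float, must_include) -> np.ndarray:
    """Integration time grid: fine steps inside [fine_lo, fine_hi] (the
    chemotherapy window, where hazards are largest), coarse steps elsewhere;
    sampling days always land exactly on grid points."""
    pts = {t0, t_end}
    pts.update(float(d) for d in must_include if t0 <= d <= t_end)
    for p in (fine_lo, fine_hi):
        if t0 < p < t_end:
            pts.add(float(p))
    bounds = sorted(pts)
    segs = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        inside = a >= fine_lo - 1e-9 and b <= fine_hi + 1e-9
        d = dt_fine if inside else dt_coarse
        n = max(1, int(round((b - a) / d)))
        segs.append(np.linspace(a, b, n + 1)[:-1])
    segs.append(np.array([t_end]))
    return np.round(np.concatenate(segs), 9)


def _transplant(founders: CloneTable, n_transplanted: int,
                rng: np.random.Generator) -> CloneTable:
    """Subsample (or proportionally expand) the founder pool for transplant."""
    total = founders.total_burden
    if n_transplanted <= 0:
        raise ValueError("n_transplanted must be >= 1")
    if n_transplanted <= total:
        pool = np.concatenate([founders.n_H, founders.n_L])
        draw = _multivariate_hypergeometric(rng, pool, n_transplanted)
        k = founders.n_clones
        tab = CloneTable(founders.clone_id, draw[:k], draw[k:], 0.0, dict(founders.meta))
    else:
        # in-vitro expansion phase: clone sizes grow proportionally and the
        # transplant aliquot is a multinomial draw over (clone, state) cells
        pool = np.concatenate([founders.n_H, founders.n_L]).astype(np.float64)
        draw = rng.multinomial(n_transplanted, pool / pool.sum())
        k = founders.n_clones
        tab = CloneTable(founders.clone_id, draw[:k], draw[k:], 0.0, dict(founders.meta))
    return tab.drop_extinct()
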