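"""Reaction-coordinate statistics and transition-state-ensemble analytics.

The reaction coordinate is Q, the number of native contacts formed in a
snapshot (a contact i–j counts as *kept* when the Cα separation satisfies
r ≤ λ·r0 with λ = 1.2 by default).  From a Q trace this module builds

* the apparent free-energy profile F(Q) = −k_B·T_avg · ln P(Q),
* the transition-state ensemble (TSE): snapshots in the probability valley
  between the unfolded and folded peaks of P(Q),
* per-residue φ-values, φ = ⟨N_i⟩_TSE / N_i^native,
* per-contact native-state probability changes between two TSEs, and the
  representative native-contact numbers h_p resolved by secondary-structure
  element pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .structures import InputError, NativeTopology, SecondaryStructureMap

#: Default contact-kept tolerance: a contact is retained while r ≤ λ·r0.
KEPT_LAMBDA = 1.2


class SelectionError(ValueError):
    """P(Q) is not bimodal, so no transition-state region exists."""


# ---------------------------------------------------------------------------
# Q traces and kept flags


@dataclass
class QTrace:
    """Per-snapshot native-contact counts with the native total NC."""

    q_counts: np.ndarray
    nc: int

    def __post_init__(self) -> None:
        self.q_counts = np.asarray(self.q_counts, dtype=np.int64)
        if self.q_counts.size and (self.q_counts.min() < 0
                                   or self.q_counts.max() > self.nc):
            raise InputError("Q counts outside [0, NC]")

    @property
    def q_fractions(self) -> np.ndarray:
        return self.q_counts / self.nc

    def __len__(self) -> int:
        return len(self.q_counts)


def contact_kept(r: np.ndarray | float, r0: np.ndarray | float,
                 lam: float = KEPT_LAMBDA) -> np.ndarray | bool:
    """Kept-in-native flag(s): r ≤ λ·r0 (boundary counts as kept)."""
    if lam <= 1:
        raise InputError("kept tolerance λ must exceed 1")
    return np.asarray(r) <= lam * np.asarray(r0)


def kept_flags(coords: np.ndarray, topo: NativeTopology,
               lam: float = KEPT_LAMBDA) -> np.ndarray:
    """(n_snapshots, n_contacts) boolean kept matrix from Cα snapshots."""
    ci, cj, cr0, _ = topo.contact_index_arrays()
    coords = np.asarray(coords, dtype=float)
    d = coords[:, ci, :] - coords[:, cj, :]
    r = np.sqrt((d * d).sum(axis=2))
    return contact_kept(r, cr0[None, :], lam)


# ---------------------------------------------------------------------------
# Histogram peak structure


def smooth_histogram(counts: np.ndarray) -> np.ndarray:
    """3-bin moving average (edges keep partial windows)."""
    c = np.asarray(counts, dtype=float)
    if len(c) < 3:
        return c.copy()
    sm = np.convolve(c, np.ones(3), mode="same")
    norm = np.convolve(np.ones_like(c), np.ones(3), mode="same")
    return sm / norm


def find_two_peaks(counts: np.ndarray,
                   smooth: bool = True) -> tuple[int, int, int, np.ndarray]:
    """Locate the two-peak structure of a Q histogram.

    Returns (low_peak, valley, high_peak, smoothed_histogram) where the
    valley is the global minimum of the smoothed histogram strictly between
    the two peaks.  Raises :class:`SelectionError` when no second mode with
    positive prominence exists.
    """
    h = smooth_histogram(counts) if smooth else np.asarray(counts, dtype=float)
    if len(h) < 3:
        raise SelectionError("histogram too short for two-peak structure")
    p1 = int(np.argmax(h))
    best = None          # (prominence, second_peak, valley)
    for b in range(len(h)):
        if abs(b - p1) < 2:
            continue
        lo, hi = (b, p1) if b < p1 else (p1, b)
        between = h[lo + 1:hi]
        vpos = lo + 1 + int(np.argmin(between))
        vmin = h[vpos]
        if h[b] <= vmin:
            continue
        prom = min(h[b], h[p1]) - vmin
        if prom <= 0:
            continue
        if best is None or prom > best[0] + 1e-12:
            best = (prom, b, vpos)
    if best is None:
        raise SelectionError("Q histogram is unimodal: no valley between peaks")
    _, b, valley = best
    low_peak, high_peak = (b, p1) if b < p1 else (p1, b)
    return low_peak, valley, high_peak, h


# ---------------------------------------------------------------------------
# Free energy and TSE selection


@dataclass
class FreeEnergyProfile:
    """Apparent free energy −k_B·T_avg·ln P(Q) on populated Q bins."""

    q_bins: np.ndarray          # populated Q counts
    f_values: np.ndarray        # reduced energy, offset so min = 0
    t_avg: float
    nc: int
    counts: np.ndarray          # raw histogram over the populated bins

    @property
    def q_fractions(self) -> np.ndarray:
        return self.q_bins / self.nc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "q_count": self.q_bins,
            "q_fraction": self.q_fractions,
            "count": self.counts,
            "free_energy": self.f_values,
        })


@dataclass
class TSESelection:
    """Snapshots at the free-energy barrier between the two P(Q) peaks."""

    indices: np.ndarray         # snapshot indices into the source trace
    q_window: tuple[int, int]   # inclusive Q-count window
    low_peak: int
    valley: int
    high_peak: int

    def __len__(self) -> int:
        return len(self.indices)


def free_energy_profile(q: QTrace, t_avg: float) -> FreeEnergyProfile:
    """Histogram P over Q-count bins of width 1; F = −k_B·T_avg·ln P,
    shifted so the lowest populated bin sits at zero."""
    if t_avg <= 0:
        raise InputError("t_avg must be positive")
    counts = np.bincount(q.q_counts, minlength=q.nc + 1)
    populated = np.nonzero(counts)[0]
    if len(populated) == 0:
        raise InputError("empty Q trace")
    p = counts[populated] / counts.sum()
    f = -t_avg * np.log(p)
    f -= f.min()
    return FreeEnergyProfile(
        q_bins=populated, f_values=f, t_avg=t_avg, nc=q.nc,
        counts=counts[populated],
    )


def select_tse(q: QTrace, t_avg: float = 1.0,
               delta: float | None = None) -> TSESelection:
    """Select TSE snapshots: Q bins strictly between the two P(Q) peaks whose
    free energy lies within ``delta`` (default 0.5·k_B·T_avg) of the barrier
    top at the valley."""
    if delta is None:
        delta = 0.5 * t_avg
    counts = np.bincount(q.q_counts, minlength=q.nc + 1)
    low_peak, valley, high_peak, smoothed = find_two_peaks(counts)
    # free energy on populated bins only; the barrier top is the highest
    # populated point strictly between the peaks
    between = [b for b in range(low_peak + 1, high_peak) if counts[b] > 0]
    if not between:
        raise SelectionError("no populated bins in the barrier region")
    with np.errstate(divide="ignore"):
        f = -t_avg * np.log(counts / counts.sum())
    f_barrier = max(f[b] for b in between)
    eligible = [b for b in between if f[b] >= f_barrier - delta]
    window = (min(eligible), max(eligible))
    mask = np.isin(q.q_counts, eligible)
    return TSESelection(
        indices=np.nonzero(mask)[0], q_window=window,
        low_peak=low_peak, valley=valley, high_peak=high_peak,
    )


# ---------------------------------------------------------------------------
# φ-values


@dataclass
class PhiProfile:
    """Per-residue φ ∈ [0, 1]; NaN marks residues with no native contacts."""

    phi: np.ndarray
    native_counts: np.ndarray
    tse_size: int

    @property
    def defined(self) -> np.ndarray:
        return self.native_counts > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "residue": np.arange(1, len(self.phi) + 1),
            "phi": self.phi,
            "native_contacts": self.native_counts,
        })


def phi_values(tse_kept: np.ndarray, topo: NativeTopology) -> PhiProfile:
    """φ_i = ⟨N_i⟩_TSE / N_i^native from the TSE kept-flag matrix
    (n_tse_snapshots × n_contacts)."""
    tse_kept = np.asarray(tse_kept, dtype=bool)
    if tse_kept.ndim != 2 or tse_kept.shape[0] == 0:
        raise InputError("TSE kept-flag matrix must be non-empty and 2-D")
    if tse_kept.shape[1] != topo.n_contacts:
        raise InputError("kept-flag matrix does not match the contact list")
    ci, cj, _, _ = topo.contact_index_arrays()
    mean_kept = tse_kept.mean(axis=0)
    n_i = np.zeros(topo.n_residues)
    for k in range(len(ci)):
        n_i[ci[k]] += mean_kept[k]
        n_i[cj[k]] += mean_kept[k]
    native = topo.native_contact_counts().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(native > 0, n_i / native, np.nan)
    return PhiProfile(phi=phi, native_counts=native.astype(np.int64),
                      tse_size=tse_kept.shape[0])


@dataclass
class PhiComparison:
    pearson_r: float
    increments: np.ndarray      # b − a per residue, NaN where undefined
    mean_increment: float
    std_increment: float
    n_defined: int


def compare_phi(a: PhiProfile, b: PhiProfile) -> PhiComparison:
    """Pearson correlation and per-residue increments b − a over residues
    where both profiles are defined."""
    if len(a.phi) != len(b.phi):
        raise InputError("φ-profiles have different residue counts")
    mask = a.defined & b.defined & np.isfinite(a.phi) & np.isfinite(b.phi)
    if mask.sum() < 3:
        raise InputError("fewer than 3 jointly defined residues")
    inc = np.where(mask, b.phi - a.phi, np.nan)
    xa, xb = a.phi[mask], b.phi[mask]
    if np.std(xa) == 0 or np.std(xb) == 0:
        r = 1.0 if np.allclose(xa - xa.mean(), xb - xb.mean()) else np.nan
    else:
        r = float(stats.pearsonr(xa, xb).statistic)
    return PhiComparison(
        pearson_r=r,
        increments=inc,
        mean_increment=float(np.nanmean(inc)),
        std_increment=float(np.nanstd(inc)),
        n_defined=int(mask.sum()),
    )


# ---------------------------------------------------------------------------
# Contact-probability changes and h_p


def contact_probability_increase(
    kept_a: np.ndarray, kept_b: np.ndarray, topo: NativeTopology
) -> np.ndarray:
    """Δprob per native contact: P_b(kept in TSE) − P_a(kept in TSE)."""
    kept_a = np.asarray(kept_a, dtype=bool)
    kept_b = np.asarray(kept_b, dtype=bool)
    if kept_a.shape[0] == 0 or kept_b.shape[0] == 0:
        raise InputError("both TSEs must be non-empty")
    if kept_a.shape[1] != topo.n_contacts or kept_b.shape[1] != topo.n_contacts:
        raise InputError("kept matrices do not match the contact list")
    return kept_b.mean(axis=0) - kept_a.mean(axis=0)


@dataclass
class HpTable:
    """h_p per secondary-structure element pair and threshold p.

    ``counts[p]`` is a symmetric (k × k) integer matrix; the diagonal holds
    intra-element contacts (counted once).  ``signed[p]`` additionally
    subtracts the number of contacts whose probability *decreased* by at
    least p, to permit the signed reading of the tabulated quantities.
    """

    labels: list[str]
    thresholds: list[float]
    counts: dict[float, np.ndarray]
    signed: dict[float, np.ndarray]

    def totals(self, p: float) -> np.ndarray:
        """Per-element totals: sum over partners including the diagonal."""
        return self.counts[p].sum(axis=1)

    def to_frame(self, p: float, signed: bool = False) -> pd.DataFrame:
        m = self.signed[p] if signed else self.counts[p]
        return pd.DataFrame(m, index=self.labels, columns=self.labels)


def h_p_table(
    dprob: np.ndarray,
    topo: NativeTopology,
    ss: SecondaryStructureMap,
    thresholds: tuple[float, ...] = (0.05, 0.10),
) -> HpTable:
    """Count native contacts with Δprob ≥ p, resolved by the unordered pair
    of secondary-structure elements the contact bridges."""
    for p in thresholds:
        if not 0 < p < 1:
            raise InputError("thresholds must lie in (0, 1)")
    if ss.n_residues != topo.n_residues:
        raise InputError("secondary-structure map does not cover the chain")
    labels = ss.labels
    k = len(labels)
    pos = {lab: idx for idx, lab in enumerate(labels)}
    dprob = np.asarray(dprob, dtype=float)
    if len(dprob) != topo.n_contacts:
        raise InputError("Δprob length does not match the contact list")

    counts = {p: np.zeros((k, k), dtype=np.int64) for p in thresholds}
    signed = {p: np.zeros((k, k), dtype=np.int64) for p in thresholds}
    for c, dp in zip(topo.contacts, dprob):
        ea = pos[ss.element_of(c.i)]
        eb = pos[ss.element_of(c.j)]
        lo, hi = min(ea, eb), max(ea, eb)
        for p in thresholds:
            inc = 1 if dp >= p else 0
            dec = 1 if dp <= -p else 0
            counts[p][lo, hi] += inc
            signed[p][lo, hi] += inc - dec
            if lo != hi:
                counts[p][hi, lo] += inc
                signed[p][hi, lo] += inc - dec
    return HpTable(labels=labels, thresholds=list(thresholds),
                   counts=counts, signed=signed)


# ---------------------------------------------------------------------------
# Two-state landscape summary


@dataclass
class TwoStateSummary:
    """Positions (Q fraction) of the basins and barrier of −lnP(Q)."""

    q_unfolded: float
    q_folded: float
    q_barrier: float
    barrier_from_folded: float     # F(barrier) − F(folded basin minimum)
    barrier_from_unfolded: float


def two_state_summary(q: QTrace, t_avg: float) -> TwoStateSummary:
    counts = np.bincount(q.q_counts, minlength=q.nc + 1)
    low_peak, valley, high_peak, smoothed = find_two_peaks(counts)
    with np.errstate(divide="ignore"):
        f = -t_avg * np.log(smoothed / smoothed.sum())
    return TwoStateSummary(
        q_unfolded=low_peak / q.nc,
        q_folded=high_peak / q.nc,
        q_barrier=valley / q.nc,
        barrier_from_folded=float(f[valley] - f[high_peak]),
        barrier_from_unfolded=float(f[valley] - f[low_peak]),
    )
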