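"""Kimura 2-parameter distances with pairwise deletion and barcode-gap analysis.

The K2P model separates transitions (A<->G, C<->T) from transversions.  With
P and Q the per-site proportions of transition and transversion differences
over the L_comp sites comparable for a pair,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Pairwise deletion: for each pair independently, any column where either
sequence carries a gap or ambiguity code is excluded; ambiguity codes are
never partially matched.

Divergence summaries follow the two conventions of barcode-gap studies:
the intraspecific set pools every within-species pairwise distance over all
species with >= 2 members, while the interspecific set holds ONE value per
unordered species pair (the mean over all cross-species pairs), so a
library of k species yields C(k, 2) interspecific comparisons.  Pairs whose
distance is undefined (no comparable sites) or saturated (the K2P logs'
arguments are non-positive) are flagged, excluded from every summary, and
counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .seqio import Library
from ._encoding import A, C, G, T, encode, encode_many


@dataclass(frozen=True)
class PairwiseComparison:
    """Site classification and K2P distance for one sequence pair."""

    P: float
    Q: float
    L_comp: int
    d: float  # nan when undefined or saturated
    undefined: bool = False  # no comparable sites
    saturated: bool = False  # K2P correction diverges


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray           # K2P distances, nan where flagged
    comparable_sites: np.ndarray
    undefined: np.ndarray        # boolean masks, symmetric
    saturated: np.ndarray

    def __post_init__(self):
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def pair(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    @property
    def n_flagged_pairs(self) -> int:
        mask = (self.undefined | self.saturated)
        return int(np.triu(mask, k=1).sum())

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path, sep="\t")

    def to_phylip(self, path) -> None:
        """Lower-triangle PHYLIP-style matrix."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                row = " ".join(f"{self.values[i, j]:.6f}" for j in range(i))
                fh.write(f"{lab:<12s} {row}".rstrip() + "\n")


@dataclass(frozen=True)
class DivergenceSummary:
    """Mean/SD/min/max of a distance set, in percent (SD with ddof=1)."""

    mean: float
    sd: float
    min: float
    max: float
    n: int
    empty: bool = False

    @staticmethod
    def of(values_pct: np.ndarray) -> "DivergenceSummary":
        v = np.asarray(values_pct, dtype=float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            return DivergenceSummary(math.nan, math.nan, math.nan, math.nan, 0, empty=True)
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        return DivergenceSummary(float(v.mean()), sd, float(v.min()), float(v.max()), int(v.size))


def _k2p_from_counts(ts: float, tv: float, L: float) -> tuple[float, float, float, bool, bool]:
    """(P, Q, d, undefined, saturated) from transition/transversion/site counts."""
    if L == 0:
        return math.nan, math.nan, math.nan, True, False
    P, Q = ts / L, tv / L
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return P, Q, math.nan, False, True
    return P, Q, (-0.5 * math.log(w1) - 0.25 * math.log(w2)) + 0.0, False, False


def k2p(seq_a: str, seq_b: str) -> PairwiseComparison:
    """K2P distance between two equal-length aligned sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must share an alignment frame (equal padded length)")
    a, b = encode(seq_a), encode(seq_b)
    both = (a < 4) & (b < 4)
    L = int(both.sum())
    if L == 0:
        return PairwiseComparison(math.nan, math.nan, 0, math.nan, undefined=True)
    av, bv = a[both], b[both]
    diff = av != bv
    transition = diff & (((av == A) & (bv == G)) | ((av == G) & (bv == A))
                         | ((av == C) & (bv == T)) | ((av == T) & (bv == C)))
    ts = int(transition.sum())
    tv = int(diff.sum()) - ts
    P, Q, d, und, sat = _k2p_from_counts(ts, tv, L)
    return PairwiseComparison(P, Q, L, d, und, sat)


def _pairwise_arrays(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(transitions, transversions, comparable) count matrices via one-hot products."""
    onehot = [(mat == b).astype(np.float64) for b in (A, C, G, T)]
    valid = (mat < 4).astype(np.float64)
    comp = valid @ valid.T
    match = sum(x @ x.T for x in onehot)
    xa, xc, xg, xt = onehot
    ts = xa @ xg.T + xg @ xa.T + xc @ xt.T + xt @ xc.T
    tv = comp - match - ts
    return ts, tv, comp


def distance_matrix_from_encoded(mat: np.ndarray, labels: list[str]) -> DistanceMatrix:
    ts, tv, comp = _pairwise_arrays(mat)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(comp > 0, ts / comp, np.nan)
        Q = np.where(comp > 0, tv / comp, np.nan)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = np.where((w1 > 0) & (w2 > 0),
                     (-0.5 * np.log(np.abs(w1)) - 0.25 * np.log(np.abs(w2))) + 0.0,
                     np.nan)
    undefined = comp == 0
    saturated = (comp > 0) & ((w1 <= 0) | (w2 <= 0))
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(undefined, False)
    np.fill_diagonal(saturated, False)
    return DistanceMatrix(labels, d, comp.astype(np.int64), undefined, saturated)


def distance_matrix(lib: Library) -> DistanceMatrix:
    """All-pairs K2P matrix under pairwise deletion."""
    if len(lib) < 2:
        raise ValueError("distance matrix requires at least 2 records")
    mat = encode_many([r.sequence for r in lib])
    return distance_matrix_from_encoded(mat, lib.ids)


def _intra_values_pct(dm: DistanceMatrix, species_of: Mapping[str, str]) -> tuple[np.ndarray, list[tuple[str, str, str]]]:
    """Pooled within-species distances (%) and (id_a, id_b, species) provenance."""
    vals, prov = [], []
    n = len(dm.labels)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = dm.labels[i], dm.labels[j]
            if species_of[a] == species_of[b] and not (dm.undefined[i, j] or dm.saturated[i, j]):
                vals.append(dm.values[i, j] * 100.0)
                prov.append((a, b, species_of[a]))
    return np.asarray(vals), prov


def _inter_values_pct(dm: DistanceMatrix, species_of: Mapping[str, str]) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """One mean distance (%) per unordered species pair."""
    by_sp: dict[str, list[int]] = {}
    for idx, lab in enumerate(dm.labels):
        by_sp.setdefault(species_of[lab], []).append(idx)
    species = sorted(by_sp)
    vals, pairs = [], []
    flagged = dm.undefined | dm.saturated
    for i, sa in enumerate(species):
        for sb in species[i + 1:]:
            block = dm.values[np.ix_(by_sp[sa], by_sp[sb])]
            ok = ~flagged[np.ix_(by_sp[sa], by_sp[sb])]
            if ok.any():
                vals.append(float(block[ok].mean()) * 100.0)
            else:
                vals.append(math.nan)
            pairs.append((sa, sb))
    return np.asarray(vals), pairs


def divergence_summaries(
    dm: DistanceMatrix, species_of: Mapping[str, str]
) -> tuple[DivergenceSummary, DivergenceSummary]:
    """(intraspecific, interspecific) divergence summaries in percent."""
    intra, _ = _intra_values_pct(dm, species_of)
    inter, _ = _inter_values_pct(dm, species_of)
    return DivergenceSummary.of(intra), DivergenceSummary.of(inter)


@dataclass
class OverlapResult:
    n_intra_total: int
    n_intra_in_window: int
    n_inter_total: int
    n_inter_in_window: int
    offending_taxa: list[str]          # species in intra hits
    offending_pairs: list[tuple[str, str]]  # species pairs in inter hits


def overlap_analysis(
    dm: DistanceMatrix,
    species_of: Mapping[str, str],
    window_lo_pct: float = 2.0,
    window_hi_pct: float = 4.0,
    closed: bool = True,
) -> OverlapResult:
    """Count distances falling in the intra/inter overlap window.

    The window is closed ([lo, hi]) by default; set ``closed=False`` for an
    open interval.
    """
    if not window_lo_pct < window_hi_pct:
        raise ValueError("window_lo_pct must be < window_hi_pct")
    intra, intra_prov = _intra_values_pct(dm, species_of)
    inter, inter_pairs = _inter_values_pct(dm, species_of)

    def in_window(v: np.ndarray) -> np.ndarray:
        if closed:
            return (v >= window_lo_pct) & (v <= window_hi_pct)
        return (v > window_lo_pct) & (v < window_hi_pct)

    intra_hit = in_window(intra) if intra.size else np.zeros(0, bool)
    finite = ~np.isnan(inter) if inter.size else np.zeros(0, bool)
    inter_hit = np.zeros_like(finite)
    if inter.size:
        inter_hit[finite] = in_window(inter[finite])
    taxa = sorted({intra_prov[i][2] for i in np.flatnonzero(intra_hit)})
    pairs = [inter_pairs[i] for i in np.flatnonzero(inter_hit)]
    return OverlapResult(
        n_intra_total=int(intra.size),
        n_intra_in_window=int(intra_hit.sum()),
        n_inter_total=int(inter.size),
        n_inter_in_window=int(inter_hit.sum()),
        offending_taxa=taxa,
        offending_pairs=pairs,
    )


def histogram_export(
    dm: DistanceMatrix,
    species_of: Mapping[str, str],
    bin_width_pct: float = 0.5,
) -> pd.DataFrame:
    """Barcode-gap histogram: intra and inter counts per divergence bin.

    Bins are [lo, hi) except the last, which is closed so totals conserve.
    """
    if bin_width_pct <= 0:
        raise ValueError("bin_width_pct must be > 0")
    intra, _ = _intra_values_pct(dm, species_of)
    inter, _ = _inter_values_pct(dm, species_of)
    inter = inter[~np.isnan(inter)] if inter.size else inter
    top = max([v.max() for v in (intra, inter) if v.size], default=0.0)
    n_bins = max(1, int(math.ceil(top / bin_width_pct)) or 1)
    if top >= n_bins * bin_width_pct:  # max exactly on the edge
        n_bins += 1
    edges = np.arange(n_bins + 1) * bin_width_pct
    intra_counts, _ = np.histogram(intra, bins=edges) if intra.size else (np.zeros(n_bins, int), edges)
    inter_counts, _ = np.histogram(inter, bins=edges) if inter.size else (np.zeros(n_bins, int), edges)
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "intra_count": intra_counts,
            "inter_count": inter_counts,
        }
    )
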