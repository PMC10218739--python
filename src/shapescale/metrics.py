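"""Chance-corrected external partition-evaluation indices.

Two indices compare an obtained partition O against a reference R:

* ARI_fnc — the Rand index corrected for chance under the
  fixed-number-of-clusters (fnc) null: the obtained partition is a
  uniformly random set partition into exactly C non-empty clusters, so
  the probability that two given samples are co-clustered is the
  Stirling-number ratio U = S(n-1, C) / S(n, C).

* AMI_max — mutual information between the partitions, corrected by the
  exact expected MI under the fixed-marginals (hypergeometric)
  permutation model and normalized by max{H(R), H(O)}.

The fnc null is the natural one for k-means output, which always has a
fixed cluster count; no equivalent generalization is known for the MI
expectation, so AMI_max retains the permutation model.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, lgamma, log
from typing import NamedTuple

import numpy as np
from scipy.special import logsumexp


class DegenerateIndexError(ValueError):
    """The chance-corrected index is undefined (denominator zero)."""


class PairCounts(NamedTuple):
    TS: int  # co-clustered in both partitions ("true similar")
    TD: int  # split in both ("true dissimilar")
    FD: int  # together in reference, split in obtained ("false dissimilar")
    FS: int  # split in reference, together in obtained ("false similar")


@dataclass(frozen=True)
class PartitionPair:
    """A reference/obtained labeling pair with its contingency table."""

    reference: np.ndarray
    obtained: np.ndarray
    contingency: np.ndarray

    @classmethod
    def from_labels(cls, reference, obtained) -> "PartitionPair":
        ref = np.asarray(reference).ravel()
        obt = np.asarray(obtained).ravel()
        if ref.size != obt.size:
            raise ValueError("label vectors must have the same length")
        if ref.size < 2:
            raise ValueError("need at least 2 samples")
        _, ri = np.unique(ref, return_inverse=True)
        _, oi = np.unique(obt, return_inverse=True)
        cont = np.zeros((ri.max() + 1, oi.max() + 1), dtype=np.int64)
        np.add.at(cont, (ri, oi), 1)
        return cls(reference=ref, obtained=obt, contingency=cont)

    @property
    def n(self) -> int:
        return self.reference.size

    @property
    def C(self) -> int:
        """Number of non-empty clusters in the obtained partition."""
        return self.contingency.shape[1]


def pair_counts(pp: PartitionPair) -> PairCounts:
    """Exact pair-category counts from the contingency table."""
    cont = pp.contingency
    ts = int(sum(comb(int(v), 2) for v in cont.ravel()))
    together_ref = int(sum(comb(int(v), 2) for v in cont.sum(axis=1)))
    together_obt = int(sum(comb(int(v), 2) for v in cont.sum(axis=0)))
    total = comb(pp.n, 2)
    fd = together_ref - ts
    fs = together_obt - ts
    td = total - ts - fd - fs
    return PairCounts(TS=ts, TD=td, FD=fd, FS=fs)


def rand_index(pp: PartitionPair) -> float:
    pc = pair_counts(pp)
    return (pc.TS + pc.TD) / comb(pp.n, 2)


def stirling2(n: int, C: int) -> int:
    """Stirling number of the second kind S(n, C), exact.

    Computed with the standard recurrence S(i, j) = j S(i-1, j) + S(i-1, j-1)
    on Python integers, so there is no floating overflow for any n.
    """
    if not (1 <= C <= n):
        raise ValueError("require 1 <= C <= n")
    row = [1] + [0] * C  # S(0, .)
    for i in range(1, n + 1):
        new = [0] * (C + 1)
        new[0] = 0 if i else 1
        for j in range(1, min(i, C) + 1):
            new[j] = j * row[j] + row[j - 1]
        row = new
    return row[C]


def log_stirling2(n: int, C: int) -> float:
    """log S(n, C) via the signed inclusion-exclusion sum, for very large n."""
    if not (1 <= C <= n):
        raise ValueError("require 1 <= C <= n")
    j = np.arange(C)  # S(n,C) = (1/C!) sum_j (-1)^j C(C,j) (C-j)^n
    terms = np.array([lgamma(C + 1) - lgamma(jj + 1) - lgamma(C - jj + 1)
                      + n * log(C - jj) for jj in j])
    val, sign = logsumexp(terms, b=(-1.0) ** j, return_sign=True)
    return float(val - lgamma(C + 1))


def cocluster_probability_fnc(n: int, C: int) -> float:
    """U = S(n-1, C) / S(n, C): probability two samples share a cluster
    under a uniformly random partition into exactly C non-empty clusters."""
    if n > 5000:  # exact integers get slow; log-space is ample here
        return float(np.exp(log_stirling2(n - 1, C) - log_stirling2(n, C)))
    return float(Fraction(stirling2(n - 1, C), stirling2(n, C)))


def expected_rand_index_fnc(pp: PartitionPair) -> float:
    """E_fnc[RI] = U V + (1 - U)(1 - V) with V the reference co-cluster rate."""
    pc = pair_counts(pp)
    u = cocluster_probability_fnc(pp.n, pp.C)
    v = (pc.TS + pc.FD) / comb(pp.n, 2)
    return u * v + (1.0 - u) * (1.0 - v)


def ari_fnc(pp: PartitionPair) -> float:
    """Rand index adjusted under the fixed-number-of-clusters null.

    (RI - E_fnc[RI]) / (1 - E_fnc[RI]); at most 1, attained exactly when
    the two partitions are identical; negative when RI < E_fnc[RI].
    """
    ri = rand_index(pp)
    e = expected_rand_index_fnc(pp)
    if abs(1.0 - e) < 1e-15:
        raise DegenerateIndexError("E_fnc[RI] = 1; ARI_fnc undefined")
    return (ri - e) / (1.0 - e)


class MIResult(NamedTuple):
    h_ref: float
    h_obt: float
    h_joint: float
    mi: float


def mutual_information(pp: PartitionPair) -> MIResult:
    """Plug-in Shannon entropies (natural log) and MI from the contingency table."""
    p = pp.contingency / pp.n

    def entropy(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    h_ref = entropy(p.sum(axis=1))
    h_obt = entropy(p.sum(axis=0))
    h_joint = entropy(p.ravel())
    return MIResult(h_ref=h_ref, h_obt=h_obt, h_joint=h_joint,
                    mi=h_ref + h_obt - h_joint)


def expected_mi(pp: PartitionPair) -> float:
    """Exact E[MI] under the fixed-marginals permutation (hypergeometric) model.

    Cell-wise sum over all feasible co-occurrence counts n_ij, with the
    hypergeometric probability written through log-factorials.
    """
    cont = pp.contingency
    n = pp.n
    a = cont.sum(axis=1).astype(int)
    b = cont.sum(axis=0).astype(int)
    lf = np.array([lgamma(i + 1) for i in range(n + 1)])  # log i!
    total = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                logp = (lf[ai] + lf[bj] + lf[n - ai] + lf[n - bj]
                        - lf[n] - lf[nij] - lf[ai - nij] - lf[bj - nij]
                        - lf[n - ai - bj + nij])
                total += (nij / n) * log(n * nij / (ai * bj)) * np.exp(logp)
    return total


def ami_max(pp: PartitionPair) -> float:
    """AMI_max = (MI - E[MI]) / (max{H(R), H(O)} - E[MI]).

    Invariant to the logarithm base; at most 1, attained exactly for
    identical partitions; may be slightly negative when MI < E[MI].
    """
    mir = mutual_information(pp)
    emi = expected_mi(pp)
    denom = max(mir.h_ref, mir.h_obt) - emi
    if abs(denom) < 1e-15:
        raise DegenerateIndexError("max entropy equals E[MI]; AMI_max undefined")
    return (mir.mi - emi) / denom


def evaluation_report(reference, obtained) -> dict:
    """All index ingredients for one labeling pair, as a flat dict."""
    pp = PartitionPair.from_labels(reference, obtained)
    pc = pair_counts(pp)
    mir = mutual_information(pp)
    return {
        "n": pp.n, "C": pp.C,
        "TS": pc.TS, "TD": pc.TD, "FD": pc.FD, "FS": pc.FS,
        "RI": rand_index(pp),
        "E_fnc_RI": expected_rand_index_fnc(pp),
        "ARI_fnc": ari_fnc(pp),
        "H_ref": mir.h_ref, "H_obt": mir.h_obt, "H_joint": mir.h_joint,
        "MI": mir.mi, "E_MI": expected_mi(pp),
        "AMI_max": ami_max(pp),
    }
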