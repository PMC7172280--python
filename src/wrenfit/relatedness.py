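"""Pairwise relatedness from multi-allelic codominant markers.

Implements Wang's (2002) moment estimator of pairwise relatedness r for
highly polymorphic loci such as microsatellites.  The estimator works on
the *similarity mode* of a dyad's two single-locus genotypes:

    mode 1 : identical genotypes              (AiAi/AiAi or AiAj/AiAj)
    mode 2 : one homozygote, one heterozygote sharing an allele (AiAi/AiAj)
    mode 3 : two heterozygotes sharing exactly one allele       (AiAj/AiAk)
    mode 4 : no shared alleles

Under the standard two-gene/four-gene IBD model with coefficients
(phi, Delta) — phi the probability the dyad shares exactly one pair of
alleles identical by descent, Delta the probability it shares two — the
mode probabilities are linear in (phi, Delta) with coefficients that are
polynomials in the locus allele-frequency moments a_m = sum_i p_i^m:

    P(mode 1) = u1 + phi (a2 - u1)          + Delta (1 - u1)
    P(mode 2) = u2 + phi (2(a2 - a3) - u2)  - Delta u2
    P(mode 3) = u3 + phi (1 - 3 a2 + 2 a3 - u3) - Delta u3

with the unrelated-dyad probabilities

    u1 = 2 a2^2 - a4
    u2 = 4 (a3 - a4)
    u3 = 4 (a2 - a2^2 - 2 a3 + 2 a4).

(phi, Delta) are estimated by generalised least squares of the observed
mode indicators on this linear model across loci, weighting each locus's
modes by the inverse of their multinomial covariance under the unrelated
null (diag(u) - u u'), which is the efficiency weighting Wang's
construction calls for; then r = phi/2 + Delta.  Frequency moments use
the sample-size bias correction (falling-factorial unbiased estimators of
sum p^m) when frequencies come from a finite reference sample.

The estimator is unbiased but noisy per dyad; r (and the derived
inbreeding coefficient f = r/2) can legitimately be negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = 0  # allele code for an untyped gene

#: coefficient bins: (bin value, lower-exclusive edge, upper-inclusive edge)
#: The edges partition the real line; each interval is (lo, hi].
BIN_EDGES: list[tuple[float, float, float]] = [
    (0.25, 0.22, np.inf),
    (0.1875, 0.16, 0.22),
    (0.125, 0.10, 0.16),
    (0.0625, 0.04, 0.10),
    (0.0, -0.02, 0.04),
    (-0.0625, -np.inf, -0.02),
]

#: a coefficient above this lower bin edge counts as "close kin" / "inbred"
#: (the 0.125 bin or higher; operationalises f or k >~ 0.125)
CLOSE_KIN_EDGE = 0.10

#: dyads typed at fewer shared loci than this are flagged low-confidence
MIN_CONFIDENT_LOCI = 4


@dataclass(frozen=True)
class CoefficientBin:
    """One bin of the f / k binning scheme."""

    value: float
    lower: float  # exclusive
    upper: float  # inclusive

    @property
    def label(self) -> str:
        return "<=-0.0625" if self.value == -0.0625 else f"{self.value:g}"


@dataclass(frozen=True)
class RelatednessEstimate:
    """Pairwise relatedness of one dyad."""

    id_i: object
    id_j: object
    r: float
    n_loci_used: int
    low_confidence: bool = field(default=False)

    @property
    def f(self) -> float:
        """Inbreeding coefficient of an offspring of this (genetic-parent) dyad."""
        return self.r / 2.0

    @property
    def k(self) -> float:
        """Kinship of this (social-parent) dyad."""
        return self.r / 2.0


class GenotypeTable:
    """Per-individual, per-locus unordered allele pairs.

    Parameters
    ----------
    ids : sequence
        Individual identifiers (unique).
    loci : sequence of str
        Locus names.
    alleles : ndarray of shape (n_individuals, n_loci, 2)
        Positive integer allele codes; ``0`` marks a missing gene.
    """

    def __init__(self, ids, loci, alleles) -> None:
        alleles = np.asarray(alleles, dtype=np.int64)
        if alleles.shape != (len(ids), len(loci), 2):
            raise ValueError("alleles must have shape (n_individuals, n_loci, 2)")
        if alleles.size and alleles.min() < 0:
            raise ValueError("allele codes must be non-negative (0 = missing)")
        self.ids = list(ids)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("individual ids must be unique")
        self.loci = list(loci)
        self.alleles = alleles
        self._index = {ind: i for i, ind in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def genotype(self, ind) -> np.ndarray:
        """The (n_loci, 2) allele array of one individual."""
        return self.alleles[self._index[ind]]

    def rows(self, inds) -> np.ndarray:
        return self.alleles[[self._index[i] for i in inds]]

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: id, locus, allele1, allele2 (0 = missing)."""
        n, L, _ = self.alleles.shape
        return pd.DataFrame(
            {
                "id": np.repeat(self.ids, L),
                "locus": np.tile(self.loci, n),
                "allele1": self.alleles[:, :, 0].ravel(),
                "allele2": self.alleles[:, :, 1].ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenotypeTable":
        loci = list(pd.unique(frame["locus"]))
        ids = list(pd.unique(frame["id"]))
        arr = np.zeros((len(ids), len(loci), 2), dtype=np.int64)
        iidx = {v: i for i, v in enumerate(ids)}
        lidx = {v: i for i, v in enumerate(loci)}
        arr[
            [iidx[v] for v in frame["id"]],
            [lidx[v] for v in frame["locus"]],
        ] = frame[["allele1", "allele2"]].to_numpy(dtype=np.int64)
        return cls(ids, loci, arr)


@dataclass
class LocusFrequencies:
    """Per-locus allele frequencies plus the moment terms Wang's estimator needs.

    ``freq[l]`` is a vector indexed by allele code (entry 0 unused).
    ``moments[l]`` holds the (optionally bias-corrected) (a2, a3, a4).
    Monomorphic or untyped loci appear in ``skipped`` and carry no moments.
    """

    loci: list
    freq: dict
    moments: dict
    n_genes: dict
    skipped: list

    def design(self, locus) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(C, u, Vinv) for one locus: the 3x2 (phi, Delta) design, the
        unrelated-mode probabilities, and the inverse null covariance of
        the mode indicators (the GLS weight matrix)."""
        a2, a3, a4 = self.moments[locus]
        u1 = 2.0 * a2 * a2 - a4
        u2 = 4.0 * (a3 - a4)
        u3 = 4.0 * (a2 - a2 * a2 - 2.0 * a3 + 2.0 * a4)
        u = np.array([u1, u2, u3])
        phi_col = np.array([a2 - u1, 2.0 * (a2 - a3) - u2, 1.0 - 3.0 * a2 + 2.0 * a3 - u3])
        delta_col = np.array([1.0 - u1, -u2, -u3])
        C = np.column_stack([phi_col, delta_col])
        V = np.diag(u) - np.outer(u, u)
        # ridge keeps near-degenerate loci (e.g. biallelic: mode 3
        # impossible) numerically invertible without changing the estimate
        V = V + 1e-9 * np.eye(3)
        return C, u, np.linalg.inv(V)


def _corrected_moments(counts: np.ndarray, n: int) -> tuple[float, float, float]:
    """Unbiased estimators of sum p^m, m = 2..4, from allele counts of n genes."""
    out = []
    for m in (2, 3, 4):
        if n < m:
            out.append(float(np.sum((counts / n) ** m)))
            continue
        num = counts.astype(float).copy()
        den = float(n)
        for j in range(1, m):
            num *= counts - j
            den *= n - j
        out.append(float(num.sum() / den))
    return tuple(out)  # type: ignore[return-value]


def allele_frequencies(
    table: GenotypeTable,
    reference_ids=None,
    bias_correct: bool = True,
) -> LocusFrequencies:
    """Per-locus allele frequencies from a reference set of individuals.

    Missing genes are excluded.  Loci with no typed individuals, or with a
    single allele (monomorphic — uninformative for relatedness), are
    excluded with a warning and listed in ``skipped``.

    ``bias_correct`` applies the falling-factorial sample-size correction to
    the frequency moments used by :func:`wang_relatedness`; the plain
    frequency vectors are always the uncorrected sample proportions.
    """
    rows = table.alleles if reference_ids is None else table.rows(reference_ids)
    freq: dict = {}
    moments: dict = {}
    n_genes: dict = {}
    skipped: list = []
    kept: list = []
    for li, locus in enumerate(table.loci):
        genes = rows[:, li, :].ravel()
        genes = genes[genes != MISSING]
        if genes.size == 0:
            warnings.warn(f"locus {locus!r} has no typed individuals; excluded")
            skipped.append(locus)
            continue
        counts = np.bincount(genes)
        n = int(genes.size)
        p = counts / n
        if np.count_nonzero(counts[1:]) < 2:
            warnings.warn(f"locus {locus!r} is monomorphic; excluded")
            skipped.append(locus)
            continue
        freq[locus] = p
        n_genes[locus] = n
        if bias_correct:
            moments[locus] = _corrected_moments(counts[1:], n)
        else:
            moments[locus] = tuple(float(np.sum(p[1:] ** m)) for m in (2, 3, 4))
        kept.append(locus)
    return LocusFrequencies(kept, freq, moments, n_genes, skipped)


def frequencies_from_vectors(loci, vectors) -> LocusFrequencies:
    """Build :class:`LocusFrequencies` from known (population) frequency vectors.

    Each vector is indexed by allele code starting at code 1 and must sum
    to 1 (within 1e-9).  No sample-size correction is applied (the
    frequencies are treated as exact).
    """
    freq: dict = {}
    moments: dict = {}
    n_genes: dict = {}
    for locus, vec in zip(loci, vectors):
        vec = np.asarray(vec, dtype=float)
        if abs(vec.sum() - 1.0) > 1e-9 or (vec < 0).any():
            raise ValueError(f"frequency vector for locus {locus!r} must sum to 1")
        p = np.concatenate([[0.0], vec])
        freq[locus] = p
        moments[locus] = tuple(float(np.sum(vec**m)) for m in (2, 3, 4))
        n_genes[locus] = np.inf
    return LocusFrequencies(list(loci), freq, moments, n_genes, [])


def similarity_mode(gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    """Similarity mode (1..4) per locus for two (L, 2) genotype arrays;
    0 where either genotype is missing."""
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    typed = (gi != MISSING).all(axis=-1) & (gj != MISSING).all(axis=-1)
    a1, a2_ = gi[..., 0], gi[..., 1]
    b1, b2 = gj[..., 0], gj[..., 1]
    i_hom = a1 == a2_
    j_hom = b1 == b2
    in_j = lambda a: (a == b1) | (a == b2)  # noqa: E731
    inter = in_j(a1).astype(int) + ((a2_ != a1) & in_j(a2_)).astype(int)
    cat = np.full(gi.shape[:-1], 4, dtype=np.int8)
    cat[(i_hom ^ j_hom) & (inter >= 1)] = 2
    cat[(~i_hom) & (~j_hom) & (inter == 1)] = 3
    identical = (i_hom & j_hom & (a1 == b1)) | ((~i_hom) & (~j_hom) & (inter == 2))
    cat[identical] = 1
    cat[~typed] = 0
    return cat


def _locus_designs(freqs: LocusFrequencies, loci: list):
    C = np.empty((len(loci), 3, 2))
    u = np.empty((len(loci), 3))
    Vinv = np.empty((len(loci), 3, 3))
    for i, locus in enumerate(loci):
        C[i], u[i], Vinv[i] = freqs.design(locus)
    return C, u, Vinv


def _solve_dyads(M: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve the per-dyad 2x2 normal equations; returns (n, 2) (phi, Delta)."""
    det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    theta = np.empty_like(rhs)
    ok = np.abs(det) > 1e-12
    theta[ok, 0] = (M[ok, 1, 1] * rhs[ok, 0] - M[ok, 0, 1] * rhs[ok, 1]) / det[ok]
    theta[ok, 1] = (M[ok, 0, 0] * rhs[ok, 1] - M[ok, 1, 0] * rhs[ok, 0]) / det[ok]
    for i in np.nonzero(~ok)[0]:
        theta[i] = np.linalg.lstsq(M[i], rhs[i], rcond=None)[0]
    return theta


def pairwise_relatedness_many(
    gi: np.ndarray,
    gj: np.ndarray,
    freqs: LocusFrequencies,
    loci: list,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Wang estimates for n dyads.

    ``gi``, ``gj`` are (n, L, 2) genotype arrays over ``loci`` (which must
    all be present in ``freqs``; monomorphic loci must already be dropped).
    Returns (r, n_loci_used); r is NaN where a dyad shares no typed locus.
    """
    C, u, Vinv = _locus_designs(freqs, loci)
    cat = similarity_mode(gi, gj)  # (n, L)
    mask = cat > 0
    onehot = np.zeros(cat.shape + (3,))
    for m in (1, 2, 3):
        onehot[..., m - 1] = cat == m
    resid = (onehot - u[None, :, :]) * mask[..., None]
    # per-locus GLS contributions
    CtVC = np.einsum("lim,lij,ljn->lmn", C, Vinv, C)  # (L, 2, 2)
    CtV = np.einsum("lim,lij->lmj", C, Vinv)  # (L, 2, 3)
    M = np.einsum("nl,lmk->nmk", mask, CtVC)  # (n, 2, 2)
    rhs = np.einsum("lmi,nli->nm", CtV, resid)
    n_used = mask.sum(axis=1)
    theta = np.full((cat.shape[0], 2), np.nan)
    have = n_used > 0
    if have.any():
        theta[have] = _solve_dyads(M[have], rhs[have])
    r = theta[:, 0] / 2.0 + theta[:, 1]
    return r, n_used


def wang_relatedness(
    genotypes_i: np.ndarray,
    genotypes_j: np.ndarray,
    freqs: LocusFrequencies,
    loci=None,
    id_i=None,
    id_j=None,
) -> RelatednessEstimate:
    """Wang's moment estimate of pairwise relatedness for one dyad.

    ``genotypes_i``/``genotypes_j`` are (L, 2) allele arrays over ``loci``
    (default: ``freqs.loci``).  Loci missing in either individual, or
    monomorphic in the reference set, are skipped; ``n_loci_used`` records
    how many informative loci entered the estimate.

    Raises ``ValueError`` if the dyad shares no typed informative locus.
    """
    loci = list(freqs.loci) if loci is None else list(loci)
    gi = np.asarray(genotypes_i, dtype=np.int64)
    gj = np.asarray(genotypes_j, dtype=np.int64)
    keep = [i for i, locus in enumerate(loci) if locus in freqs.moments]
    gi, gj = gi[keep][None], gj[keep][None]
    kept_loci = [loci[i] for i in keep]
    r, n_used = pairwise_relatedness_many(gi, gj, freqs, kept_loci)
    if n_used[0] == 0:
        raise ValueError("dyad shares no typed informative locus; r undefined")
    return RelatednessEstimate(
        id_i=id_i,
        id_j=id_j,
        r=float(r[0]),
        n_loci_used=int(n_used[0]),
        low_confidence=bool(n_used[0] < MIN_CONFIDENT_LOCI),
    )


def dyad_table(
    table: GenotypeTable,
    pairs,
    freqs: LocusFrequencies | None = None,
) -> pd.DataFrame:
    """Relatedness estimates for many dyads of a genotype table.

    ``pairs`` is an iterable of (id_i, id_j).  Returns a frame with columns
    id_i, id_j, r, f, n_loci, bin, close_flag, low_confidence.  Dyads with
    no shared typed locus get NaN r.
    """
    if freqs is None:
        freqs = allele_frequencies(table)
    pairs = list(pairs)
    if not pairs:
        return pd.DataFrame(
            columns=["id_i", "id_j", "r", "f", "n_loci", "bin", "close_flag", "low_confidence"]
        )
    keep = [i for i, locus in enumerate(table.loci) if locus in freqs.moments]
    loci = [table.loci[i] for i in keep]
    gi = table.rows([p[0] for p in pairs])[:, keep]
    gj = table.rows([p[1] for p in pairs])[:, keep]
    r, n_used = pairwise_relatedness_many(gi, gj, freqs, loci)
    f = r / 2.0
    bins = [bin_coefficient(v).label if np.isfinite(v) else "" for v in f]
    return pd.DataFrame(
        {
            "id_i": [p[0] for p in pairs],
            "id_j": [p[1] for p in pairs],
            "r": r,
            "f": f,
            "n_loci": n_used,
            "bin": bins,
            "close_flag": np.where(np.isfinite(f), f > CLOSE_KIN_EDGE, False),
            "low_confidence": n_used < MIN_CONFIDENT_LOCI,
        }
    )


def inbreeding_from_parents(r: float) -> float:
    """Offspring inbreeding coefficient from the genetic-parent dyad: f = r/2.

    The same relation gives the social-pair kinship k = r/2.  Negative r is
    retained (f estimates may be negative).  Missing r propagates as NaN.
    """
    return float(r) / 2.0 if r is not None else float("nan")


def bin_coefficient(value: float) -> CoefficientBin:
    """Assign an f (or k) value to its coefficient bin.

    Bins are upper-inclusive with edges at 0.22, 0.16, 0.10, 0.04, -0.02:
    e.g. f = 0.10 falls in the 0.0625 bin, f = 0.23 in the 0.25 bin, and
    any f <= -0.02 in the open-ended "<=-0.0625" bin.
    """
    value = float(value)
    if not np.isfinite(value):
        raise ValueError("cannot bin a non-finite coefficient")
    for binval, lo, hi in BIN_EDGES:
        if lo < value <= hi:
            return CoefficientBin(binval, lo, hi)
    raise AssertionError("bins partition the real line")  # pragma: no cover


def classify_close(value: float) -> bool:
    """True iff the coefficient falls in the 0.125 bin or higher.

    This operationalises "highly inbred" (f >~ 0.125) for offspring and
    "close kin" (k >~ 0.125) for social pairs: the lower edge of the 0.125
    bin is 0.10, so any value strictly above 0.10 qualifies.
    """
    value = float(value)
    if not np.isfinite(value):
        raise ValueError("cannot classify a non-finite coefficient")
    return value > CLOSE_KIN_EDGE
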