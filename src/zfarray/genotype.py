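"""Diploid genotype inference from extracted ZF-array observations.

The pipeline for one individual:

1. coverage gate — individuals with fewer than 100 retained reads are
   not processed further;
2. length inference — a five-rule table on the frequencies of the most
   common array lengths (``f_i >= f_j >= f_k``) decides whether the two
   haplotypes have equal or different unit counts, absorbing PCR
   slippage products as minority lengths;
3. consensus calling — per haplotype length, a per-position majority
   consensus with consensus frequency ``f_c`` (Ns and gaps excluded
   from denominators);
4. phasing of equal-length heterozygotes — reads are reduced to the
   positions with ``f_c < 0.7``, clustered hierarchically on mismatch
   distance, and the two largest clusters are taken as the haplotypes,
   each re-checked for internal consistency.

Unequal-length allele consensi are discarded if any position has
``f_c < 0.6``; equal-length cluster consensi if any position has
``f_c < 0.7``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .catalog import ZFCatalog
from .extract import ArrayObservation

DEFAULT_MIN_COVERAGE = 100
FC_FLOOR_UNEQUAL = 0.6
FC_FLOOR_EQUAL = 0.7
MAX_CLUSTERS = 19  # cluster count searched over 1 <= n < 20
MIN_CLUSTER_SUPPORT = 2

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


# -- length-frequency table and rules ----------------------------------

@dataclass(frozen=True)
class LengthFrequencyTable:
    """Read counts and frequencies per observed array length (unit count).

    Labels i, j, k are the first, second and third most frequent lengths;
    count ties break toward the smaller unit count, deterministically.
    """

    counts: dict[int, int]

    def __post_init__(self) -> None:
        if not self.counts or any(c <= 0 for c in self.counts.values()):
            raise ValueError("counts must be non-empty with positive values")

    @classmethod
    def from_observations(cls, observations: Iterable[ArrayObservation]) -> "LengthFrequencyTable":
        return cls(dict(Counter(o.n_units for o in observations)))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def ordered(self) -> list[tuple[int, float]]:
        """(length, frequency) sorted by count desc, then length asc."""
        total = self.total
        ranked = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return [(length, cnt / total) for length, cnt in ranked]

    def top_freqs(self) -> tuple[tuple[int, float], tuple[int, float] | None, tuple[int, float] | None]:
        ranked = self.ordered
        i = ranked[0]
        j = ranked[1] if len(ranked) > 1 else None
        k = ranked[2] if len(ranked) > 2 else None
        return i, j, k


@dataclass(frozen=True)
class LengthCall:
    rule: int | None  # 1..5, or None for no_call
    hap_lengths: tuple[int, int] | None

    @property
    def is_call(self) -> bool:
        return self.rule is not None


NO_CALL = LengthCall(rule=None, hap_lengths=None)


def infer_lengths(table: LengthFrequencyTable) -> LengthCall:
    """Apply the five length rules consecutively; first satisfied rule wins.

    1. a single observed length (f_i = 1)            → (i, i)
    2. f_i + f_j >= 0.7 and f_i/f_j < 2              → (i, j)
    3. f_i + f_j >= 0.7 and f_i/f_j < 3 and f_j/f_k > 2 → (i, j)
    4. f_i + f_j >= 0.7 and f_i/f_j > 3              → (i, i)
    5. f_i >= 0.7                                    → (i, i)

    With fewer than three observed lengths f_k is treated as 0 (so
    f_j/f_k is +inf). The ratio boundaries are strict: f_i/f_j exactly 2
    escapes rule 2, exactly 3 escapes both rules 3 and 4.
    """
    (li, fi), j, k = table.top_freqs()
    if j is None:
        return LengthCall(rule=1, hap_lengths=(li, li))
    lj, fj = j
    fk = k[1] if k is not None else 0.0
    ratio_ij = fi / fj
    ratio_jk = fj / fk if fk > 0 else math.inf
    if fi + fj >= 0.7:
        if ratio_ij < 2:
            return LengthCall(rule=2, hap_lengths=(li, lj))
        if ratio_ij < 3 and ratio_jk > 2:
            return LengthCall(rule=3, hap_lengths=(li, lj))
        if ratio_ij > 3:
            return LengthCall(rule=4, hap_lengths=(li, li))
    if fi >= 0.7:
        return LengthCall(rule=5, hap_lengths=(li, li))
    return NO_CALL


def coverage_gate(
    observations: Sequence[ArrayObservation], min_coverage: int = DEFAULT_MIN_COVERAGE
) -> bool:
    """True iff at least ``min_coverage`` post-extraction reads are present."""
    return len(observations) >= min_coverage


# -- consensus ----------------------------------------------------------

@dataclass(frozen=True)
class ConsensusProfile:
    """Per-position base counts, majority consensus and consensus frequency.

    ``f_c[p]`` = count of the consensus base / count of non-N, non-gap
    observations at p; NaN where every read has N (consensus base 'N').
    """

    length: int
    base_counts: np.ndarray  # (length, 4) int
    consensus: str
    f_c: np.ndarray  # (length,) float

    def min_fc(self) -> float:
        valid = self.f_c[~np.isnan(self.f_c)]
        return float(valid.min()) if valid.size else float("nan")


def _seq_matrix(seqs: Sequence[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return arr.reshape(len(seqs), len(seqs[0]))


def build_consensus(seqs: Sequence[str]) -> ConsensusProfile:
    """Majority consensus of equal-length sequences; N and ``-`` excluded."""
    if not seqs:
        raise ValueError("need at least one sequence")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must have equal length")
    mat = _seq_matrix(seqs)
    counts = np.empty((length, 4), dtype=np.int64)
    for bi, base in enumerate(_BASES):
        counts[:, bi] = (mat == ord(base)).sum(axis=0)
    totals = counts.sum(axis=1)
    best = counts.argmax(axis=1)  # ties break toward A<C<G<T, deterministic
    with np.errstate(invalid="ignore", divide="ignore"):
        f_c = np.where(totals > 0, counts[np.arange(length), best] / totals, np.nan)
    cons = np.array(list(_BASES))[best]
    cons[totals == 0] = "N"
    return ConsensusProfile(
        length=length, base_counts=counts, consensus="".join(cons), f_c=f_c
    )


# -- equal-length phasing ----------------------------------------------

@dataclass(frozen=True)
class PhaseResult:
    status: str  # "hom" | "het" | "fail"
    consensi: tuple[str, ...] = ()
    supports: tuple[int, ...] = ()
    reason: str | None = None


def _pairwise_mismatch(mat: np.ndarray) -> np.ndarray:
    """Condensed mismatch-distance matrix; N positions excluded pairwise."""
    n = mat.shape[0]
    is_n = mat == ord("N")
    out = np.empty(n * (n - 1) // 2, dtype=float)
    idx = 0
    for a in range(n - 1):
        diff = (mat[a] != mat[a + 1 :]) & ~is_n[a] & ~is_n[a + 1 :]
        m = diff.sum(axis=1)
        out[idx : idx + m.size] = m
        idx += m.size
    return out


def _mean_within_cluster(dist_sq: np.ndarray, labels: np.ndarray) -> float:
    """Mean pairwise distance pooled over within-cluster pairs; 0 if none."""
    total = 0.0
    pairs = 0
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        if members.size < 2:
            continue
        sub = dist_sq[np.ix_(members, members)]
        iu = np.triu_indices(members.size, 1)
        total += float(sub[iu].sum())
        pairs += iu[0].size
    return total / pairs if pairs else 0.0


def phase_equal_length(
    seqs: Sequence[str],
    fc_floor: float = FC_FLOOR_EQUAL,
    max_clusters: int = MAX_CLUSTERS,
    min_support: int = MIN_CLUSTER_SUPPORT,
) -> PhaseResult:
    """Resolve a set of equal-length arrays into one (hom) or two (het)
    haplotype consensi.

    If every position has ``f_c >= fc_floor`` the individual is called
    homozygous. Otherwise reads are reduced to the low-consensus
    positions, clustered (complete-linkage on pairwise mismatches, Ns
    excluded pairwise), the cluster count n in [1, max_clusters]
    minimizing the pooled mean within-cluster distance is chosen
    (ties → smallest n), and the two largest clusters are taken as
    haplotypes. A haplotype fails if its cluster has fewer than
    ``min_support`` reads or its full-length consensus again has a
    position with ``f_c < fc_floor``.
    """
    profile = build_consensus(seqs)
    het_pos = np.where(profile.f_c < fc_floor)[0]  # NaN compares False
    if het_pos.size == 0:
        return PhaseResult(status="hom", consensi=(profile.consensus,), supports=(len(seqs),))
    if len(seqs) < 2 * min_support:
        return PhaseResult(status="fail", reason="insufficient_support")

    mat = _seq_matrix(seqs)[:, het_pos]
    condensed = _pairwise_mismatch(mat)
    from scipy.spatial.distance import squareform

    dist_sq = squareform(condensed)
    Z = linkage(condensed, method="complete")
    best_n, best_score = 1, math.inf
    n_max = min(max_clusters, len(seqs))
    for n in range(1, n_max + 1):
        labels = fcluster(Z, t=n, criterion="maxclust")
        score = _mean_within_cluster(dist_sq, labels)
        if score < best_score - 1e-12:
            best_n, best_score = n, score
    labels = fcluster(Z, t=best_n, criterion="maxclust")
    sizes = Counter(labels.tolist())
    # two largest clusters; ties break by cluster label for determinism
    top = sorted(sizes.items(), key=lambda kv: (-kv[1], kv[0]))[:2]
    if len(top) < 2 or top[1][1] < min_support or top[0][1] < min_support:
        return PhaseResult(status="fail", reason="insufficient_support")
    consensi: list[str] = []
    supports: list[int] = []
    for lab, size in top:
        members = [s for s, l in zip(seqs, labels) if l == lab]
        sub = build_consensus(members)
        if np.any(sub.f_c < fc_floor):
            return PhaseResult(status="fail", reason="inconsistent_cluster")
        consensi.append(sub.consensus)
        supports.append(size)
    if consensi[0] == consensi[1]:
        # clusters converged on one sequence: effectively homozygous
        return PhaseResult(status="hom", consensi=(consensi[0],), supports=(sum(supports),))
    return PhaseResult(status="het", consensi=tuple(consensi), supports=tuple(supports))


# -- diploid genotype ---------------------------------------------------

@dataclass
class AlleleCall:
    dna: str | None
    name: str | None
    zf_codes: list[str] = field(default_factory=list)
    support: int = 0
    qc_pass: bool = False
    reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "zf_codes": list(self.zf_codes),
            "dna": self.dna,
            "support": self.support,
            "qc_pass": self.qc_pass,
            "reason": self.reason,
        }


@dataclass
class DiploidGenotype:
    individual: str
    alleles: tuple[AlleleCall, AlleleCall]
    zygosity: str | None  # "hom" | "het_equal_length" | "het_unequal_length"
    length_call: LengthCall
    qc_pass: bool
    qc_reason: str | None = None
    n_reads: int = 0

    @property
    def allele_dnas(self) -> tuple[str | None, str | None]:
        return (self.alleles[0].dna, self.alleles[1].dna)

    def unordered_pair(self) -> frozenset | None:
        if not self.qc_pass:
            return None
        return frozenset(Counter(self.allele_dnas).items())

    def to_dict(self) -> dict:
        return {
            "individual": self.individual,
            "zygosity": self.zygosity,
            "rule": self.length_call.rule,
            "hap_lengths": list(self.length_call.hap_lengths)
            if self.length_call.hap_lengths
            else None,
            "alleles": [a.to_dict() for a in self.alleles],
            "qc_pass": self.qc_pass,
            "qc_reason": self.qc_reason,
            "n_reads": self.n_reads,
        }


def _failed_call(reason: str) -> AlleleCall:
    return AlleleCall(dna=None, name=None, qc_pass=False, reason=reason)


def _finalize_allele(dna: str, support: int, catalog: ZFCatalog) -> AlleleCall:
    if "N" in dna:
        return _failed_call("unresolved_positions")
    known = catalog.allele_by_dna(dna)
    if known is not None:
        return AlleleCall(
            dna=dna, name=known.name, zf_codes=list(known.zf_codes),
            support=support, qc_pass=True,
        )
    codes = catalog.encode_allele(dna, register_novel=True)
    allele = catalog.new_allele(codes, provenance="novel")
    return AlleleCall(
        dna=dna, name=allele.name, zf_codes=codes, support=support, qc_pass=True
    )


def call_genotype(
    individual: str,
    observations: Sequence[ArrayObservation],
    catalog: ZFCatalog,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> DiploidGenotype:
    """Orchestrate coverage gate → length rules → consensus/phasing →
    allele naming for one individual."""
    observations = sorted(observations, key=lambda o: o.read_id)
    fail = lambda reason, rule=NO_CALL: DiploidGenotype(  # noqa: E731
        individual=individual,
        alleles=(_failed_call(reason), _failed_call(reason)),
        zygosity=None,
        length_call=rule,
        qc_pass=False,
        qc_reason=reason,
        n_reads=len(observations),
    )
    if not coverage_gate(observations, min_coverage):
        return fail("insufficient_coverage")
    table = LengthFrequencyTable.from_observations(observations)
    call = infer_lengths(table)
    if not call.is_call:
        return fail("length_no_call")
    li, lj = call.hap_lengths

    def seqs_of_length(n_units: int) -> list[str]:
        return [o.normalized_dna for o in observations if o.n_units == n_units]

    if li != lj:
        zygosity = "het_unequal_length"
        allele_calls: list[AlleleCall] = []
        for n_units in (li, lj):
            seqs = seqs_of_length(n_units)
            profile = build_consensus(seqs)
            if np.any(profile.f_c < FC_FLOOR_UNEQUAL):
                allele_calls.append(_failed_call("low_consensus"))
            else:
                allele_calls.append(_finalize_allele(profile.consensus, len(seqs), catalog))
    else:
        seqs = seqs_of_length(li)
        phase = phase_equal_length(seqs)
        if phase.status == "fail":
            return fail(phase.reason or "phasing_failed", rule=call)
        if phase.status == "hom":
            zygosity = "hom"
            one = _finalize_allele(phase.consensi[0], phase.supports[0], catalog)
            allele_calls = [one, one]
        else:
            zygosity = "het_equal_length"
            allele_calls = [
                _finalize_allele(dna, sup, catalog)
                for dna, sup in zip(phase.consensi, phase.supports)
            ]
    qc_pass = all(a.qc_pass for a in allele_calls)
    qc_reason = None if qc_pass else next(
        a.reason for a in allele_calls if not a.qc_pass
    )
    return DiploidGenotype(
        individual=individual,
        alleles=(allele_calls[0], allele_calls[1]),
        zygosity=zygosity,
        length_call=call,
        qc_pass=qc_pass,
        qc_reason=qc_reason,
        n_reads=len(observations),
    )


# -- cross-platform merge ----------------------------------------------

@dataclass(frozen=True)
class ConcordanceRecord:
    individual: str
    concordant: bool
    category: str | None  # "hom" | "het_equal" | "het_unequal"
    shared_allele: bool


_CATEGORY = {
    "hom": "hom",
    "het_equal_length": "het_equal",
    "het_unequal_length": "het_unequal",
}


def merge_platform_calls(
    genotype_a: DiploidGenotype, genotype_b: DiploidGenotype
) -> tuple[DiploidGenotype, ConcordanceRecord]:
    """Compare two platform calls for the same individual.

    Concordant iff the unordered allele-DNA pairs agree; the merged call
    is the concordant genotype, else the qc-passing one (first on ties).
    """
    if genotype_a.individual != genotype_b.individual:
        raise ValueError("genotypes are for different individuals")
    pair_a, pair_b = genotype_a.unordered_pair(), genotype_b.unordered_pair()
    concordant = pair_a is not None and pair_a == pair_b
    set_a = set(d for d in genotype_a.allele_dnas if d)
    set_b = set(d for d in genotype_b.allele_dnas if d)
    shared = bool(set_a & set_b)
    category = _CATEGORY.get(genotype_a.zygosity or "", None)
    merged = genotype_a if (genotype_a.qc_pass or not genotype_b.qc_pass) else genotype_b
    return merged, ConcordanceRecord(
        individual=genotype_a.individual,
        concordant=concordant,
        category=category,
        shared_allele=shared,
    )
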