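"""Allele classification by DNA-contact residues and cohort statistics.

C2H2 zinc fingers read DNA mainly through the residues at helix
positions -1, 3 and 6 of each finger. Alleles are classified as A-type
or C-type by aligning their per-finger contact-residue triplets against
those of the two reference alleles (the two major binding
configurations in human populations) and labelling by the higher
normalized similarity.

Within each 28-residue finger the helix is located by anchoring on the
conserved C-terminal histidine pair (first His of the pair sits at
helix position 7), putting the contact residues 8, 4 and 1 positions
before it. Offsets can be overridden for non-canonical scaffolds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .catalog import ZF_UNIT_AA, Allele, CatalogError, ZFCatalog
from .genotype import DiploidGenotype

DEFAULT_TYPE_THRESHOLD = 0.5
GAP_PENALTY = -0.5


# -- contact residues ---------------------------------------------------

def locate_contact_offsets(aa_unit: str) -> tuple[int, int, int]:
    """Offsets of helix positions -1, 3, 6 within one 28-aa finger.

    The conserved His pair (H-x3-H, tolerating x4/x5) is searched from
    the C-terminus; with the first His at index h (helix position 7),
    the contacts sit at h-8, h-4 and h-1.
    """
    if len(aa_unit) != ZF_UNIT_AA:
        raise CatalogError(f"finger must be {ZF_UNIT_AA} aa, got {len(aa_unit)}")
    for h2 in range(len(aa_unit) - 1, -1, -1):
        if aa_unit[h2] != "H":
            continue
        for span in (4, 5, 6):
            h1 = h2 - span
            if h1 >= 8 and aa_unit[h1] == "H":
                return (h1 - 8, h1 - 4, h1 - 1)
    raise CatalogError("no conserved His pair found in finger")


@dataclass(frozen=True)
class ContactProfile:
    """One 3-residue token per finger (helix -1/3/6 residues)."""

    triplets: tuple[str, ...]
    offsets: tuple[int, int, int]


def contact_profile(
    allele: Allele, offsets: tuple[int, int, int] | None = None
) -> ContactProfile:
    """Contact-residue tokens for every finger of an allele, 5'→3'."""
    tokens: list[str] = []
    used: tuple[int, int, int] | None = offsets
    for i in range(allele.n_zf):
        aa = allele.aa[i * ZF_UNIT_AA : (i + 1) * ZF_UNIT_AA]
        off = offsets if offsets is not None else locate_contact_offsets(aa)
        used = off
        tokens.append("".join(aa[o] for o in off))
    assert used is not None
    return ContactProfile(triplets=tuple(tokens), offsets=used)


# -- type scoring -------------------------------------------------------

def _align_tokens(query: Sequence[str], ref: Sequence[str]) -> float:
    """Needleman-Wunsch on token lists: match 1, mismatch 0, gap -0.5."""
    nq, nr = len(query), len(ref)
    prev = np.array([GAP_PENALTY * j for j in range(nr + 1)])
    for i in range(1, nq + 1):
        cur = np.empty(nr + 1)
        cur[0] = GAP_PENALTY * i
        qi = query[i - 1]
        for j in range(1, nr + 1):
            diag = prev[j - 1] + (1.0 if qi == ref[j - 1] else 0.0)
            cur[j] = max(diag, prev[j] + GAP_PENALTY, cur[j - 1] + GAP_PENALTY)
        prev = cur
    return float(prev[nr])


@dataclass(frozen=True)
class TypeScore:
    sim_A: float
    sim_C: float
    label: str  # "A-type" | "C-type" | "untyped"


def classify_type(
    allele: Allele,
    ref_a: Allele,
    ref_c: Allele,
    threshold: float = DEFAULT_TYPE_THRESHOLD,
    offsets: tuple[int, int, int] | None = None,
) -> TypeScore:
    """Score an allele against the A and C reference contact profiles.

    Similarity to each reference is the global token-alignment score
    normalized by the reference token count (self vs self = 1). The
    label is the argmax when the maximum reaches ``threshold``;
    otherwise — or on an exact tie — the allele is untyped.
    """
    q = contact_profile(allele, offsets).triplets
    ta = contact_profile(ref_a, offsets).triplets
    tc = contact_profile(ref_c, offsets).triplets
    sim_a = _align_tokens(q, ta) / len(ta)
    sim_c = _align_tokens(q, tc) / len(tc)
    if max(sim_a, sim_c) < threshold or sim_a == sim_c:
        label = "untyped"
    elif sim_a > sim_c:
        label = "A-type"
    else:
        label = "C-type"
    return TypeScore(sim_A=sim_a, sim_C=sim_c, label=label)


def label_catalog(
    catalog: ZFCatalog,
    ref_a_name: str,
    ref_c_name: str,
    threshold: float = DEFAULT_TYPE_THRESHOLD,
    offsets: tuple[int, int, int] | None = None,
) -> dict[str, TypeScore]:
    """Classify every allele in a catalog against two named references,
    writing ``type_label`` in place and returning the scores."""
    ref_a, ref_c = catalog.alleles[ref_a_name], catalog.alleles[ref_c_name]
    scores: dict[str, TypeScore] = {}
    for allele in catalog.alleles.values():
        score = classify_type(allele, ref_a, ref_c, threshold, offsets)
        allele.type_label = score.label if score.label != "untyped" else "untyped"
        scores[allele.name] = score
    return scores


# -- catalog statistics -------------------------------------------------

def length_stats(alleles: Iterable[Allele]) -> dict:
    """Median finger count per type label plus a two-sided Wilcoxon
    rank-sum p-value (normal approximation, tie-corrected) comparing
    A-type against C-type lengths."""
    groups: dict[str, list[int]] = {}
    for al in alleles:
        groups.setdefault(al.type_label, []).append(al.n_zf)
    a = groups.get("A-type", [])
    c = groups.get("C-type", [])
    if not a or not c:
        raise ValueError("need at least one allele per type")
    res = stats.mannwhitneyu(a, c, alternative="two-sided", method="asymptotic")
    return {
        "median_A": float(np.median(a)),
        "median_C": float(np.median(c)),
        "n_A": len(a),
        "n_C": len(c),
        "p_value": float(res.pvalue),
    }


# -- population summaries -----------------------------------------------

@dataclass(frozen=True)
class FrequencyRecord:
    population: str
    allele: str
    count: int
    frequency: float
    ci99: tuple[float, float]


def _clopper_pearson(k: int, n: int, conf: float = 0.99) -> tuple[float, float]:
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (lo, hi)


def allele_frequencies(
    genotypes_by_population: Mapping[str, Sequence[DiploidGenotype]],
    conf: float = 0.99,
) -> list[FrequencyRecord]:
    """Per-population allele frequencies with exact binomial CIs.

    Each qc-passing individual contributes exactly two allele copies;
    qc-failed genotypes are excluded.
    """
    records: list[FrequencyRecord] = []
    for pop, genotypes in genotypes_by_population.items():
        counts: dict[str, int] = {}
        n_chrom = 0
        for g in genotypes:
            if not g.qc_pass:
                continue
            for call in g.alleles:
                counts[call.name] = counts.get(call.name, 0) + 1
                n_chrom += 1
        for allele, k in sorted(counts.items()):
            records.append(
                FrequencyRecord(
                    population=pop,
                    allele=allele,
                    count=k,
                    frequency=k / n_chrom,
                    ci99=_clopper_pearson(k, n_chrom, conf),
                )
            )
    return records


def heterozygosity(
    genotypes_by_population: Mapping[str, Sequence[DiploidGenotype]]
) -> dict[str, float]:
    """Fraction of qc-passing individuals whose two allele DNAs differ."""
    out: dict[str, float] = {}
    for pop, genotypes in genotypes_by_population.items():
        passing = [g for g in genotypes if g.qc_pass]
        if not passing:
            out[pop] = float("nan")
            continue
        het = sum(1 for g in passing if g.alleles[0].dna != g.alleles[1].dna)
        out[pop] = het / len(passing)
    return out


# -- trios and set concordance ------------------------------------------

def trio_concordance(
    child: DiploidGenotype, mother: DiploidGenotype, father: DiploidGenotype
) -> tuple[bool, tuple[str, str] | None]:
    """Mendelian consistency of a child's diploid call with its parents.

    Consistent iff the child's allele pair can be split with one allele
    drawn from the mother's pair and the other from the father's
    (identity on DNA). Returns the (maternal, paternal) assignment of
    the child's alleles when consistent.
    """
    c1, c2 = child.allele_dnas
    m = set(mother.allele_dnas)
    f = set(father.allele_dnas)
    for a, b in ((c1, c2), (c2, c1)):
        if a in m and b in f:
            return True, (a, b)
    return False, None


def compare_genotype_sets(
    set1: Mapping[str, DiploidGenotype], set2: Mapping[str, DiploidGenotype]
) -> dict:
    """Concordance between two genotype call sets sharing individual ids.

    Returns per-zygosity-category and overall percent concordance plus
    the annotated discordant individuals.
    """
    from .genotype import merge_platform_calls

    shared = sorted(set(set1) & set(set2))
    per_cat: dict[str, list[bool]] = {}
    discordant: list[dict] = []
    n_conc = 0
    for ind in shared:
        _, rec = merge_platform_calls(set1[ind], set2[ind])
        per_cat.setdefault(rec.category or "unknown", []).append(rec.concordant)
        if rec.concordant:
            n_conc += 1
        else:
            discordant.append(
                {"individual": ind, "shared_allele": rec.shared_allele}
            )
    return {
        "n": len(shared),
        "n_concordant": n_conc,
        "overall_pct": 100.0 * n_conc / len(shared) if shared else float("nan"),
        "by_category": {
            cat: 100.0 * sum(v) / len(v) for cat, v in sorted(per_cat.items())
        },
        "discordant": discordant,
    }
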