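"""Synthetic ZF catalogs, diploid individuals and barcoded long reads.

Everything downstream of wet-lab sequencing can be exercised without
external data: fingers are random 84-nt units sharing a fixed C2H2-like
scaffold (so units are homologous, as in a real minisatellite), alleles
are unit strings, and reads are full amplicons — outer barcode, inner
barcode, 5' flank, array, 3' flank, reverse-complemented barcodes —
with per-base errors, whole-unit PCR slippage and occasional 3'
truncation, the artifact classes the genotyper's filters are built to
absorb.

All outputs are reproducible from (parameters, seed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .catalog import ZF_UNIT_NT, Allele, ZFCatalog, ZincFinger
from .extract import (
    FLANK3,
    FLANK5,
    BarcodeScheme,
    revcomp,
)
from .switches import DEFAULT_MIN_MATCH, Segment, SwitchPath

# 28-aa scaffold with contact residues (helix -1/3/6) at indices 15/19/22
# and the conserved His pair at 23/27. Codons are fixed except at the
# contact positions and two wobble sites, keeping fingers >= 85% identical.
_SCAFFOLD_AA = "TGEKPYVCRECGRGF?KSN?LL?HQRTH"
_CONTACT_IDX = (15, 19, 22)
_WOBBLE_IDX = (17, 21)  # silent third-base variation at these codons
_CONTACT_AA_POOL_A = "RSDEN"  # token alphabet for A-like fingers
_CONTACT_AA_POOL_C = "QKTVA"  # disjoint alphabet for C-like fingers

_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}
_WOBBLE = {"S": ("TCT", "TCA", "TCC", "TCG"), "L": ("CTG", "CTA", "CTT", "CTC")}


def _finger_dna(contacts: str, rng: random.Random) -> str:
    codons: list[str] = []
    ci = iter(contacts)
    for idx, aa in enumerate(_SCAFFOLD_AA):
        if idx in _CONTACT_IDX:
            codons.append(_CODON[next(ci)])
        elif idx in _WOBBLE_IDX:
            codons.append(rng.choice(_WOBBLE[_SCAFFOLD_AA[idx]]))
        else:
            codons.append(_CODON[aa])
    dna = "".join(codons)
    assert len(dna) == ZF_UNIT_NT
    return dna


def simulate_catalog(
    n_fingers: int = 12,
    n_alleles: int = 8,
    length_range: tuple[int, int] = (10, 16),
    seed: int = 0,
) -> ZFCatalog:
    """Random homologous fingers plus random-unit-string alleles.

    Fingers share the scaffold (pairwise identity well above 60%);
    alleles are named S1, S2, ... with lengths uniform in
    ``length_range``.
    """
    if n_fingers < 2:
        raise ValueError("need at least two fingers")
    rng = random.Random(seed)
    catalog = ZFCatalog()
    seen: set[str] = set()
    idx = 0
    while len(catalog.fingers) < n_fingers:
        contacts = "".join(rng.choice(_CONTACT_AA_POOL_A + _CONTACT_AA_POOL_C) for _ in range(3))
        dna = _finger_dna(contacts, rng)
        if dna in seen:
            continue
        seen.add(dna)
        idx += 1
        catalog.add_finger(ZincFinger(code=f"s{idx:02d}", dna=dna))
    codes = list(catalog.fingers)
    for ai in range(n_alleles):
        n = rng.randint(*length_range)
        zf_codes = [rng.choice(codes) for _ in range(n)]
        dna = catalog.build_dna(zf_codes)
        if catalog.allele_by_dna(dna) is not None:
            zf_codes[rng.randrange(n)] = rng.choice(codes)
            dna = catalog.build_dna(zf_codes)
        catalog.add_allele(
            Allele(
                name=f"S{ai + 1}",
                zf_codes=zf_codes,
                dna=dna,
                provenance="synthetic",
            )
        )
    return catalog


def simulate_typed_catalog(
    n_a: int = 50,
    n_c: int = 21,
    a_length: int = 13,
    c_length: int = 15,
    seed: int = 0,
) -> tuple[ZFCatalog, str, str]:
    """A two-family allele catalog emulating the human situation.

    Two reference alleles, ``A`` (``a_length`` fingers, default 13) and
    ``C`` (``c_length`` fingers, default 15), are built from disjoint
    contact-residue alphabets. The remaining alleles are variants made
    by single-finger substitutions, duplications and deletions of their
    family's reference, so family sizes (default 50 A-like, 21 C-like)
    and median lengths mirror the catalog the genotyping study
    assembled. Returns (catalog, ref_a_name, ref_c_name).
    """
    rng = random.Random(seed)
    catalog = ZFCatalog()

    def mint_finger(pool: str, prefix: str) -> str:
        while True:
            contacts = "".join(rng.choice(pool) for _ in range(3))
            dna = _finger_dna(contacts, rng)
            if catalog.finger_by_dna(dna) is None:
                code = f"{prefix}{len(catalog.fingers) + 1:02d}"
                catalog.add_finger(ZincFinger(code=code, dna=dna))
                return code

    a_pool = [mint_finger(_CONTACT_AA_POOL_A, "a") for _ in range(8)]
    c_pool = [mint_finger(_CONTACT_AA_POOL_C, "c") for _ in range(8)]

    def make_family(
        ref_name: str, pool: list[str], n_total: int, ref_len: int, label: str
    ) -> str:
        ref_codes = [rng.choice(pool) for _ in range(ref_len)]
        catalog.add_allele(
            Allele(
                name=ref_name,
                zf_codes=ref_codes,
                dna=catalog.build_dna(ref_codes),
                provenance="synthetic",
                type_label=label,
            )
        )
        made = 1
        v = 0
        while made < n_total:
            v += 1
            codes = list(ref_codes)
            op = rng.random()
            if op < 0.4:  # substitute one finger within the family pool
                codes[rng.randrange(len(codes))] = rng.choice(pool)
            elif op < 0.7:  # tandem-duplicate one finger
                i = rng.randrange(len(codes))
                codes.insert(i, codes[i])
            else:  # delete one finger
                if len(codes) > 2:
                    codes.pop(rng.randrange(len(codes)))
            dna = catalog.build_dna(codes)
            if catalog.allele_by_dna(dna) is not None:
                continue
            catalog.add_allele(
                Allele(
                    name=f"{ref_name}v{v}",
                    zf_codes=codes,
                    dna=dna,
                    provenance="synthetic",
                    type_label=label,
                )
            )
            made += 1
        return ref_name

    ref_a = make_family("A", a_pool, n_a, a_length, "A-type")
    ref_c = make_family("C", c_pool, n_c, c_length, "C-type")
    return catalog, ref_a, ref_c


# -- recombinants -------------------------------------------------------

def simulate_recombinant(
    p1: str,
    p2: str,
    k_switches: int,
    min_match: int = DEFAULT_MIN_MATCH,
    seed: int = 0,
) -> tuple[str, SwitchPath]:
    """Plant a child with exactly ``k_switches + 1`` alternating fragments.

    Fragment lengths are random but each strictly exceeds ``min_match``;
    the first starts at parent 1's 5' end (start parent alternates with
    the seed), the last ends at a parent's 3' end. The planted path is
    the construction truth; a solver may still find a cheaper one if the
    junction contexts are not unique.
    """
    if k_switches < 0:
        raise ValueError("k_switches must be >= 0")
    rng = random.Random(seed)
    parents = (p1, p2)
    frag = min_match + 1
    need = [len(p) for p in parents]
    if min(need) < (k_switches + 1) * frag:
        raise ValueError("parents too short to host this many switches")
    start = rng.randint(0, 1)
    segments: list[Segment] = []
    child_parts: list[str] = []
    active = start
    if k_switches == 0:
        segments.append(Segment(start + 1, 0, len(parents[start])))
        child_parts.append(parents[start])
    else:
        # first fragment: anchored prefix
        l0 = rng.randint(frag, len(parents[active]) - frag)
        segments.append(Segment(active + 1, 0, l0))
        child_parts.append(parents[active][:l0])
        for step in range(1, k_switches + 1):
            active = 1 - active
            p = parents[active]
            last = step == k_switches
            if last:
                s = rng.randint(0, len(p) - frag)
                segments.append(Segment(active + 1, s, len(p)))
                child_parts.append(p[s:])
            else:
                l = rng.randint(frag, max(frag, len(p) // max(2, k_switches)))
                s = rng.randint(0, len(p) - l)
                segments.append(Segment(active + 1, s, s + l))
                child_parts.append(p[s : s + l])
    child = "".join(child_parts)
    path = SwitchPath(child=child, parents=parents, segments=tuple(segments))
    path.validate(min_match)
    return child, path


# -- read simulation ----------------------------------------------------

@dataclass(frozen=True)
class ErrorModel:
    """Per-base error rates plus amplicon-level artifact probabilities."""

    substitution: float = 0.01
    insertion: float = 0.005
    deletion: float = 0.005
    slippage: float = 0.10  # whole-unit gain/loss per read
    slip_shifts: tuple[int, ...] = (-2, -1, 1, 2)
    slip_weights: tuple[float, ...] = (0.1, 0.4, 0.4, 0.1)
    truncation: float = 0.02  # read loses its 3' end (and hence flank3)

    def __post_init__(self) -> None:
        for r in (self.substitution, self.insertion, self.deletion):
            if not 0.0 <= r < 1.0:
                raise ValueError("per-base rates must be in [0, 1)")
        for r in (self.slippage, self.truncation):
            if not 0.0 <= r <= 1.0:
                raise ValueError("per-read probabilities must be in [0, 1]")


ERROR_FREE = ErrorModel(substitution=0.0, insertion=0.0, deletion=0.0,
                        slippage=0.0, truncation=0.0)


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    individual: str
    haplotype: int  # 0 or 1
    slip_shift: int  # units gained (+) or lost (-); 0 = faithful
    truncated: bool


def _apply_base_errors(seq: str, model: ErrorModel, rng: random.Random) -> str:
    if model.substitution == model.insertion == model.deletion == 0.0:
        return seq
    out: list[str] = []
    p_del = model.deletion
    p_ins = p_del + model.insertion
    p_sub = p_ins + model.substitution
    for base in seq:
        r = rng.random()
        if r < p_del:
            continue
        if r < p_ins:
            out.append(rng.choice("ACGT"))
            out.append(base)
        elif r < p_sub:
            out.append(rng.choice([b for b in "ACGT" if b != base]))
        else:
            out.append(base)
    return "".join(out)


def _slip_array(units: list[str], shift: int, rng: random.Random) -> list[str]:
    units = list(units)
    if shift > 0:
        for _ in range(shift):
            i = rng.randrange(len(units))
            units.insert(i, units[i])  # tandem duplication
    else:
        for _ in range(-shift):
            if len(units) > 1:
                units.pop(rng.randrange(len(units)))
    return units


def simulate_reads(
    individual: str,
    allele_dnas: tuple[str, str],
    coverage: int,
    barcode_pair: tuple[int, int] = (0, 0),
    scheme: BarcodeScheme | None = None,
    error_model: ErrorModel = ErrorModel(),
    seed: int = 0,
    with_barcodes: bool = True,
) -> tuple[list[tuple[str, str]], list[ReadTruth]]:
    """Simulate ``coverage`` amplicon reads for one diploid individual.

    Haplotypes are drawn 50/50; each read is barcode+flank+array+flank+
    barcode (barcodes omitted when ``with_barcodes`` is False), with
    slippage applied at the unit level before per-base errors, and
    occasional truncation removing the 3' flank. Half the reads are
    emitted reverse-complemented.
    """
    scheme = scheme or BarcodeScheme()
    rng = random.Random(seed)
    outer = scheme.outer[barcode_pair[0]]
    inner = scheme.inner[barcode_pair[1]]
    reads: list[tuple[str, str]] = []
    truths: list[ReadTruth] = []
    for ri in range(coverage):
        hap = rng.randint(0, 1)
        units = [
            allele_dnas[hap][i : i + ZF_UNIT_NT]
            for i in range(0, len(allele_dnas[hap]), ZF_UNIT_NT)
        ]
        shift = 0
        if rng.random() < error_model.slippage:
            shift = rng.choices(error_model.slip_shifts, error_model.slip_weights)[0]
            shift = max(shift, 1 - len(units))
            units = _slip_array(units, shift, rng)
        core = FLANK5 + "".join(units) + FLANK3
        if with_barcodes:
            core = outer + inner + core + revcomp(inner) + revcomp(outer)
        truncated = rng.random() < error_model.truncation
        if truncated:
            keep = len(core) - rng.randint(
                len(FLANK3) // 2, len(FLANK3) + (len(inner) + len(outer) if with_barcodes else 0)
            )
            core = core[:keep]
        seq = _apply_base_errors(core, error_model, rng)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        read_id = f"{individual}_r{ri:05d}"
        reads.append((read_id, seq))
        truths.append(ReadTruth(read_id, individual, hap, shift, truncated))
    return reads, truths


@dataclass
class SimulatedCohort:
    """Reads plus generation truth for a set of diploid individuals."""

    reads_by_individual: dict[str, list[tuple[str, str]]]
    truth_genotypes: dict[str, tuple[str, str]]  # individual -> allele dna pair
    read_truth: list[ReadTruth] = field(default_factory=list)


def simulate_cohort(
    catalog: ZFCatalog,
    n_individuals: int = 200,
    coverage: int = 150,
    error_model: ErrorModel = ErrorModel(),
    hom_fraction: float = 0.3,
    seed: int = 0,
    with_barcodes: bool = False,
) -> SimulatedCohort:
    """Random diploid individuals drawn from a catalog's alleles.

    ``hom_fraction`` of individuals are homozygous; the rest draw two
    distinct alleles (so equal-length heterozygotes occur whenever the
    catalog holds same-length allele pairs).
    """
    rng = random.Random(seed)
    alleles = list(catalog.alleles.values())
    if len(alleles) < 2:
        raise ValueError("catalog needs at least two alleles")
    cohort = SimulatedCohort({}, {})
    for i in range(n_individuals):
        name = f"ind{i:04d}"
        if rng.random() < hom_fraction:
            a = b = rng.choice(alleles)
        else:
            a, b = rng.sample(alleles, 2)
        pair = (a.dna, b.dna)
        reads, truths = simulate_reads(
            name,
            pair,
            coverage,
            barcode_pair=(i % 96, (i // 96) % 8),
            error_model=error_model,
            seed=rng.randrange(2**31),
            with_barcodes=with_barcodes,
        )
        cohort.reads_by_individual[name] = reads
        cohort.truth_genotypes[name] = pair
        cohort.read_truth.extend(truths)
    return cohort


def write_fastq(reads: Sequence[tuple[str, str]], path: str) -> None:
    """Plain FASTQ with uniform dummy qualities."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
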