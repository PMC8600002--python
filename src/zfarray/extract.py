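"""Locate and tile the ZF array in raw amplicon long reads.

The amplicon places the zinc-finger minisatellite between two fixed
genomic flanks. A read is usable only if both flanks are found (either
orientation) in order; the interval strictly between them is then tiled
5'→3' into 84-nt repeat units by aligning catalog fingers, padding
read gaps with Ns so every unit is exactly 84 characters. Reads failing
any step are rejected with a reason — PCR slippage products of the
wrong *length* survive this filter on purpose and are removed later by
the genotyper's length-frequency rules.

Demultiplexing uses a dual barcode scheme: eight 12-nt inner barcodes
(added with the locus primers) combined with outer barcodes from a
second PCR round, addressing ``8 x n_outer`` samples (768 with a
96-barcode outer set).
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from typing import Iterable

import edlib

from .catalog import ZF_UNIT_NT, ZFCatalog

# Genomic sequence immediately 5' of the ZF array (read retention requires it).
FLANK5 = (
    "CACAGCCGTAATGACAAAACCAAAGGTCAAGAGATCAAAGAAAGGTCCAAACTCTTGAATAAAAGGACATGGCAGA"
    "GGGAGATTTCAAGGGCCTTTTCTAGCCCACCCAAAGGACAAATGGGGAGCTGTAGAGTGGGAAAAAGAATAATGGA"
    "AGAAGAGTCCAGAACAGGCCAGAAAGTGAATCCAGGGAACACAGGCAAATTATTTGTGGGGGTAGGAATCTCAAGA"
    "ATTGCAAAAGTCAAGTATGGAGAG"
)

# Genomic sequence immediately 3' of the ZF array.
FLANK3 = (
    "GATGAGTAAGTCATTAGTAATAAAACCTCATCTCAATAGCCACAAAAAGACAAATGTGGTCACCACACACTTGCAC"
    "ACCCCAGCTGTGAGGTGGCTTCAGCGGAAGTCTGCTGACCCCTTATATTCCCCGAGAGTATAAAGAGATCGGAAAT"
    "AACTGATTAAACAAATCCGCCACTTTCATGACTAGAGATGAGGAAGAACAAGGGATAGTTCTGTAAGTGTTCGGGG"
    "GACATCAGCATGTGTGGTTCTTTC"
)

# The eight 12-nt inner barcodes added with the locus primers.
INNER_BARCODES = (
    "ATCACGATCACG",
    "CGATGTCGATGT",
    "GATCAGGATCAG",
    "CTTGTACTTGTA",
    "ACAGTGACAGTG",
    "GCCAATGCCAAT",
    "CAGATCCAGATC",
    "ACTTGAACTTGA",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _make_outer_barcodes(n: int = 96, length: int = 24, min_dist: int = 8) -> tuple[str, ...]:
    """Synthetic outer-barcode set (the production scheme uses a vendor
    96-barcode kit; these deterministic stand-ins have the same geometry)."""
    rng = random.Random(96024)
    codes: list[str] = []
    while len(codes) < n:
        cand = "".join(rng.choice("ACGT") for _ in range(length))
        if all(sum(a != b for a, b in zip(cand, c)) >= min_dist for c in codes):
            codes.append(cand)
    return tuple(codes)


#: 96 synthetic 24-nt outer barcodes (deterministic).
OUTER_BARCODES = _make_outer_barcodes()


@dataclass(frozen=True)
class BarcodeScheme:
    """Dual barcode scheme: outer (2nd-round) x inner (primer) barcodes."""

    inner: tuple[str, ...] = INNER_BARCODES
    outer: tuple[str, ...] = OUTER_BARCODES
    max_mismatch_inner: int = 1
    max_mismatch_outer: int = 2
    front_window: int = 100

    def __post_init__(self) -> None:
        if len(set(self.inner)) != len(self.inner):
            raise ValueError("inner barcodes must be pairwise distinct")
        if len(set(self.outer)) != len(self.outer):
            raise ValueError("outer barcodes must be pairwise distinct")

    @property
    def capacity(self) -> int:
        """Number of addressable samples (8 x 96 = 768 with the defaults)."""
        return len(self.inner) * len(self.outer)

    def sample_id(self, outer_idx: int, inner_idx: int) -> str:
        """1-based ``{outer}_{inner}`` label, e.g. ``07_3``."""
        return f"{outer_idx + 1:02d}_{inner_idx + 1}"


@dataclass(frozen=True)
class FlankAnchors:
    """The two genomic anchors delimiting the ZF array, with an identity floor."""

    flank5: str = FLANK5
    flank3: str = FLANK3
    min_identity: float = 0.75

    def __post_init__(self) -> None:
        if not self.flank5 or not self.flank3:
            raise ValueError("flank anchors must be non-empty")
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class FlankHit:
    start: int  # 0-based, half-open on the read
    end: int
    identity: float
    strand: str = "+"


@dataclass(frozen=True)
class ArrayObservation:
    """One read's extracted, unit-normalized ZF array."""

    read_id: str
    array_dna: str
    units: tuple[str, ...]
    flank5_identity: float
    flank3_identity: float
    strand: str

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def normalized_dna(self) -> str:
        """Ns mark read gaps; length is always 84 x n_units."""
        return "".join(self.units)


REJECTION_REASONS = (
    "no_flank5",
    "no_flank3",
    "disordered_flanks",
    "non_contiguous_array",
)


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str


# -- flank finding ------------------------------------------------------

def _best_infix(anchor: str, read: str) -> tuple[int, int, float] | None:
    res = edlib.align(anchor, read, mode="HW", task="locations")
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    identity = 1.0 - res["editDistance"] / len(anchor)
    return start, end + 1, identity


def find_flank(read: str, anchor: str, min_identity: float = 0.75) -> FlankHit | None:
    """Best local placement of ``anchor`` in ``read`` or its reverse
    complement; ``None`` when identity over the anchor falls below the floor."""
    if not anchor:
        raise ValueError("anchor must be non-empty")
    best: FlankHit | None = None
    for strand, seq in (("+", read), ("-", revcomp(read))):
        hit = _best_infix(anchor, seq)
        if hit is None:
            continue
        start, end, ident = hit
        if best is None or ident > best.identity:
            best = FlankHit(start, end, ident, strand)
    if best is None or best.identity < min_identity:
        return None
    return best


# -- unit tiling --------------------------------------------------------

class TilingError(ValueError):
    pass


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _normalize_unit(finger_dna: str, segment: str, cigar: str) -> str:
    """Project a read segment onto finger coordinates: matches/mismatches
    keep the read base, read gaps become N, read insertions are dropped."""
    out: list[str] = []
    t = 0
    for count, op in _CIGAR_RE.findall(cigar):
        n = int(count)
        if op in ("=", "X", "M"):
            out.append(segment[t : t + n])
            t += n
        elif op == "I":  # query (finger) base with no read base: gap in read
            out.append("N" * n)
        else:  # "D": extra read base, not part of the unit
            t += n
    unit = "".join(out)
    assert len(unit) == len(finger_dna)
    return unit


def tile_units(
    array_dna: str,
    catalog: ZFCatalog,
    min_identity: float = 0.75,
    min_unit_coverage: float = 0.5,
) -> list[str]:
    """Greedy 5'→3' decomposition of an inter-flank interval into 84-nt units.

    At each offset the best-matching catalog finger is aligned as a prefix
    of the remaining sequence (edit distance, full-finger alignment). A unit
    is accepted if identity >= ``min_identity`` and it consumes at least
    ``min_unit_coverage`` of 84 read bases; partial units (read gaps) are
    padded to 84 with Ns. Any uncovered interior gap fails the whole array
    (strict contiguity).
    """
    if not array_dna:
        raise TilingError("empty array interval")
    max_dist = int(ZF_UNIT_NT * (1.0 - min_identity))
    min_consumed = int(ZF_UNIT_NT * min_unit_coverage)
    units: list[str] = []
    off = 0
    n = len(array_dna)
    while off < n:
        window = array_dna[off : off + ZF_UNIT_NT + max_dist + 4]
        # fast path: exact 84-mer already in the catalog
        exact = window[:ZF_UNIT_NT]
        if len(exact) == ZF_UNIT_NT and catalog.finger_by_dna(exact) is not None:
            units.append(exact)
            off += ZF_UNIT_NT
            continue
        best_dist = max_dist + 1
        best: tuple[str, str, int] | None = None  # (finger dna, cigar, consumed)
        for zf in catalog.fingers.values():
            res = edlib.align(zf.dna, window, mode="SHW", task="path", k=best_dist - 1)
            d = res["editDistance"]
            if d < 0 or d >= best_dist:
                continue
            consumed = res["locations"][0][1] + 1
            best_dist = d
            best = (zf.dna, res["cigar"], consumed)
            if d == 0:
                break
        if best is None:
            raise TilingError(
                f"no catalog finger tiles offset {off} (identity floor {min_identity})"
            )
        finger_dna, cigar, consumed = best
        if consumed < min_consumed:
            raise TilingError(f"unit at offset {off} covers only {consumed} nt")
        units.append(_normalize_unit(finger_dna, window[:consumed], cigar))
        off += consumed
    return units


# -- array extraction ---------------------------------------------------

def extract_array(
    read_id: str,
    seq: str,
    anchors: FlankAnchors,
    catalog: ZFCatalog,
    min_identity: float = 0.75,
    min_unit_coverage: float = 0.5,
) -> ArrayObservation | Rejection:
    """Extract the ZF array strictly between the two flank anchors.

    Orientation is resolved by whichever strand yields both flanks in
    order; the array is reported on the + (flank5 → flank3) orientation.
    """
    seq = seq.upper()
    found5 = found3 = False
    best: tuple[float, str, FlankHit, FlankHit] | None = None
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        h5 = _best_infix(anchors.flank5, s)
        h3 = _best_infix(anchors.flank3, s)
        ok5 = h5 is not None and h5[2] >= anchors.min_identity
        ok3 = h3 is not None and h3[2] >= anchors.min_identity
        found5 |= ok5
        found3 |= ok3
        if ok5 and ok3 and h5[1] <= h3[0]:
            score = h5[2] + h3[2]
            if best is None or score > best[0]:
                best = (
                    score,
                    strand,
                    FlankHit(h5[0], h5[1], h5[2], strand),
                    FlankHit(h3[0], h3[1], h3[2], strand),
                )
    if best is None:
        if not found5:
            return Rejection(read_id, "no_flank5")
        if not found3:
            return Rejection(read_id, "no_flank3")
        return Rejection(read_id, "disordered_flanks")
    _, strand, hit5, hit3 = best
    s = seq if strand == "+" else revcomp(seq)
    array_dna = s[hit5.end : hit3.start]
    try:
        units = tile_units(
            array_dna,
            catalog,
            min_identity=min_identity,
            min_unit_coverage=min_unit_coverage,
        )
    except TilingError:
        return Rejection(read_id, "non_contiguous_array")
    return ArrayObservation(
        read_id=read_id,
        array_dna=array_dna,
        units=tuple(units),
        flank5_identity=hit5.identity,
        flank3_identity=hit3.identity,
        strand=strand,
    )


def extract_all(
    reads: Iterable[tuple[str, str]],
    anchors: FlankAnchors,
    catalog: ZFCatalog,
    **kwargs,
) -> tuple[list[ArrayObservation], list[Rejection]]:
    """Extract every read; returns (observations, rejections)."""
    obs: list[ArrayObservation] = []
    rej: list[Rejection] = []
    for read_id, seq in reads:
        result = extract_array(read_id, seq, anchors, catalog, **kwargs)
        if isinstance(result, ArrayObservation):
            obs.append(result)
        else:
            rej.append(result)
    return obs, rej


# -- demultiplexing -----------------------------------------------------

def _scan_barcode(
    window: str, barcodes: tuple[str, ...], budget: int
) -> int | None:
    """Index of the unique best-matching barcode within ``budget`` edits;
    ``None`` if none qualifies or two tie at the minimum."""
    best_dist = budget + 1
    best_idx: int | None = None
    tie = False
    for idx, bc in enumerate(barcodes):
        res = edlib.align(bc, window, mode="HW", task="distance", k=budget)
        d = res["editDistance"]
        if d < 0:
            continue
        if d < best_dist:
            best_dist, best_idx, tie = d, idx, False
        elif d == best_dist:
            tie = True
    if tie:
        return None
    return best_idx


@dataclass
class DemuxResult:
    assigned: dict[tuple[int, int], list[tuple[str, str]]] = field(default_factory=dict)
    unassigned: list[tuple[str, str]] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out = {"unassigned": len(self.unassigned)}
        for key, reads in sorted(self.assigned.items()):
            out[f"{key[0] + 1:02d}_{key[1] + 1}"] = len(reads)
        return out


def demultiplex(
    reads: Iterable[tuple[str, str]], scheme: BarcodeScheme
) -> DemuxResult:
    """Assign reads to (outer, inner) sample bins.

    A read is assigned iff exactly one (outer, inner) pair matches inside
    the front window of either orientation within the mismatch budgets;
    orientation disagreement or within-set ties send it to unassigned.
    """
    result = DemuxResult()
    w = scheme.front_window
    outer_index = {bc: i for i, bc in enumerate(scheme.outer)}
    inner_index = {bc: i for i, bc in enumerate(scheme.inner)}
    lo, li = len(scheme.outer[0]), len(scheme.inner[0])
    for read_id, seq in reads:
        seq = seq.upper()
        pairs: set[tuple[int, int]] = set()
        for s in (seq, revcomp(seq)):
            # fast path: error-free barcodes at the expected positions
            o_exact = outer_index.get(s[:lo])
            if o_exact is not None:
                i_exact = inner_index.get(s[lo : lo + li])
                if i_exact is not None:
                    pairs.add((o_exact, i_exact))
                    continue
            front = s[:w]
            o = _scan_barcode(front, scheme.outer, scheme.max_mismatch_outer)
            i = _scan_barcode(front, scheme.inner, scheme.max_mismatch_inner)
            if o is not None and i is not None:
                pairs.add((o, i))
        if len(pairs) == 1:
            result.assigned.setdefault(pairs.pop(), []).append((read_id, seq))
        else:
            result.unassigned.append((read_id, seq))
    return result
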