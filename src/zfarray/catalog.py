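"""Data model and I/O for PRDM9-style zinc-finger (ZF) catalogs.

A PRDM9 allele is defined by the DNA sequence of its C2H2 zinc-finger
minisatellite: a tandem array of 84-bp repeat units, each encoding a
28-residue finger. Distinct 84-bp units carry short two-character codes
(historically single characters; two characters leave room for growth),
so an allele can be written compactly as an ordered code string. Units
never seen before are minted codes of the form ``!X``; alleles never
seen before are named ``M1``, ``M2``, ... in discovery order.

File formats are deliberately plain: tab-separated tables with a header
row (columns ``code, dna, source`` for fingers; ``name, zf_codes,
provenance, type_label`` for alleles, with ``zf_codes`` comma-joined) or
FASTA with the code/name as the record id.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

ZF_UNIT_NT = 84
ZF_UNIT_AA = 28

#: Distance (bp) from the forward primer to the start of the ZF array and
#: from the end of the array to the reverse primer, in the amplicon design
#: used for genotyping (hg38 reference allele).
UPSTREAM_FLANK_BP = 670
DOWNSTREAM_FLANK_BP = 137

_DNA_ALPHABET = frozenset("ACGT")

PROVENANCES = ("population", "sperm", "blood", "novel", "synthetic")
TYPE_LABELS = ("A-type", "C-type", "untyped", "unclassified")


class CatalogError(ValueError):
    """Malformed or inconsistent catalog data."""


def amplicon_length(n_zf: int) -> int:
    """Expected amplicon length (bp) for an allele of ``n_zf`` fingers.

    The reference 13-finger allele yields an 84*13 = 1,092 bp array and,
    with the 670 bp upstream / 137 bp downstream primer-to-array flanks,
    a 1,899 bp amplicon.
    """
    if n_zf < 1:
        raise ValueError("allele must contain at least one zinc finger")
    return ZF_UNIT_NT * n_zf + UPSTREAM_FLANK_BP + DOWNSTREAM_FLANK_BP


def translate_unit(dna: str) -> str:
    """Translate one 84-nt unit in frame 0; stop codons are an error."""
    if len(dna) != ZF_UNIT_NT:
        raise CatalogError(f"ZF unit must be {ZF_UNIT_NT} nt, got {len(dna)}")
    aa = str(Seq(dna).translate())
    if "*" in aa:
        raise CatalogError("ZF unit translation contains a stop codon")
    return aa


@dataclass(frozen=True)
class ZincFinger:
    """One 84-bp repeat unit of the ZF array."""

    code: str
    dna: str
    is_novel: bool = False

    def __post_init__(self) -> None:
        if len(self.dna) != ZF_UNIT_NT:
            raise CatalogError(
                f"ZF {self.code!r}: dna must be {ZF_UNIT_NT} nt, got {len(self.dna)}"
            )
        bad = set(self.dna) - _DNA_ALPHABET
        if bad:
            raise CatalogError(f"ZF {self.code!r}: non-ACGT characters {sorted(bad)}")
        translate_unit(self.dna)  # validates: no stop codon in frame 0

    @property
    def aa(self) -> str:
        return translate_unit(self.dna)


@dataclass
class Allele:
    """A named allele: an ordered ZF-code string plus its concatenated DNA."""

    name: str
    zf_codes: list[str]
    dna: str
    provenance: str = "population"
    type_label: str = "unclassified"

    def __post_init__(self) -> None:
        if not self.zf_codes:
            raise CatalogError(f"allele {self.name!r}: needs at least one ZF")
        if len(self.dna) != ZF_UNIT_NT * len(self.zf_codes):
            raise CatalogError(
                f"allele {self.name!r}: dna length {len(self.dna)} != "
                f"{ZF_UNIT_NT} x {len(self.zf_codes)}"
            )
        if self.provenance not in PROVENANCES:
            raise CatalogError(f"allele {self.name!r}: bad provenance {self.provenance!r}")
        if self.type_label not in TYPE_LABELS:
            raise CatalogError(f"allele {self.name!r}: bad type_label {self.type_label!r}")

    @property
    def n_zf(self) -> int:
        return len(self.zf_codes)

    @property
    def aa(self) -> str:
        return "".join(
            translate_unit(self.dna[i : i + ZF_UNIT_NT])
            for i in range(0, len(self.dna), ZF_UNIT_NT)
        )


@dataclass(frozen=True)
class VariantName:
    """Five-part name for de-novo variants observed in sperm or blood.

    Rendered ``<type>:<s|c>:<number>:<donor>:<parent1-parent2>``, e.g. a
    complex A-derived variant #65 from the sperm of man 2, whose diploid
    genotype was A/L20, renders ``Av:c:0065:M2S:A-L20``. Figures use the
    short form ``Av:0065``.
    """

    variant_type: str  # e.g. "Av", "Cv", "Rv" (recombinant), "Uv" (unknown)
    complexity: str  # "s"imple or "c"omplex
    allele_number: int
    donor: str  # man + tissue, e.g. "M2S" (sperm) or "M7B" (blood)
    parental_genotype: tuple[str, str]

    def __post_init__(self) -> None:
        if self.complexity not in ("s", "c"):
            raise CatalogError("complexity must be 's' or 'c'")
        if self.allele_number < 0:
            raise CatalogError("allele_number must be non-negative")

    def render(self) -> str:
        return (
            f"{self.variant_type}:{self.complexity}:{self.allele_number:04d}:"
            f"{self.donor}:{self.parental_genotype[0]}-{self.parental_genotype[1]}"
        )

    def short(self) -> str:
        return f"{self.variant_type}:{self.allele_number:04d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


# Novel-finger code space: "!A".."!Z" as published, extended with lowercase
# then digits so simulators cannot exhaust it prematurely.
_NOVEL_SUFFIXES = string.ascii_uppercase + string.ascii_lowercase + string.digits


class ZFCatalog:
    """A validated collection of zinc fingers and the alleles built from them."""

    def __init__(
        self,
        fingers: Iterable[ZincFinger] = (),
        alleles: Iterable[Allele] = (),
    ) -> None:
        self.fingers: dict[str, ZincFinger] = {}
        self.alleles: dict[str, Allele] = {}
        self._dna_to_code: dict[str, str] = {}
        for zf in fingers:
            self.add_finger(zf)
        for al in alleles:
            self.add_allele(al)

    # -- construction -------------------------------------------------

    def add_finger(self, zf: ZincFinger) -> None:
        if zf.code in self.fingers:
            raise CatalogError(f"duplicate ZF code {zf.code!r}")
        if zf.dna in self._dna_to_code:
            raise CatalogError(
                f"ZF {zf.code!r} duplicates the dna of {self._dna_to_code[zf.dna]!r}"
            )
        self.fingers[zf.code] = zf
        self._dna_to_code[zf.dna] = zf.code

    def add_allele(self, allele: Allele) -> None:
        if allele.name in self.alleles:
            raise CatalogError(f"duplicate allele name {allele.name!r}")
        for code in allele.zf_codes:
            if code not in self.fingers:
                raise CatalogError(
                    f"allele {allele.name!r} references unknown ZF {code!r}"
                )
        expect = self.build_dna(allele.zf_codes)
        if expect != allele.dna:
            raise CatalogError(
                f"allele {allele.name!r}: dna does not match its zf_codes"
            )
        self.alleles[allele.name] = allele

    def build_dna(self, zf_codes: Sequence[str]) -> str:
        return "".join(self.fingers[c].dna for c in zf_codes)

    def new_allele(
        self,
        zf_codes: Sequence[str],
        provenance: str = "novel",
        type_label: str = "unclassified",
    ) -> Allele:
        """Register (or look up) the allele with this code string."""
        name = self.name_new_allele(zf_codes)
        if name in self.alleles:
            return self.alleles[name]
        allele = Allele(
            name=name,
            zf_codes=list(zf_codes),
            dna=self.build_dna(zf_codes),
            provenance=provenance,
            type_label=type_label,
        )
        self.add_allele(allele)
        return allele

    # -- lookups -------------------------------------------------------

    def finger_by_dna(self, dna: str) -> ZincFinger | None:
        code = self._dna_to_code.get(dna)
        return self.fingers[code] if code is not None else None

    def allele_by_dna(self, dna: str) -> Allele | None:
        for allele in self.alleles.values():
            if allele.dna == dna:
                return allele
        return None

    # -- nomenclature --------------------------------------------------

    def mint_zf_code(self) -> str:
        """Next unused novel-finger code: !A..!Z, then !a..!z, then !0..!9."""
        for suffix in _NOVEL_SUFFIXES:
            code = "!" + suffix
            if code not in self.fingers:
                return code
        raise CatalogError("novel ZF code space exhausted")

    def name_new_allele(self, zf_codes: Sequence[str]) -> str:
        """Name for this code string: the existing name on an exact match,
        otherwise the next free ``M#`` index (deterministic in catalog state)."""
        codes = list(zf_codes)
        for allele in self.alleles.values():
            if allele.zf_codes == codes:
                return allele.name
        idx = 1
        while f"M{idx}" in self.alleles:
            idx += 1
        return f"M{idx}"

    # -- encoding ------------------------------------------------------

    def encode_allele(self, dna: str, register_novel: bool = True) -> list[str]:
        """Decompose an array DNA into ordered ZF codes, 5'→3'.

        Each 84-nt unit is mapped to an existing finger on exact match;
        otherwise a novel ``!%`` finger is minted and (by default) added
        to the catalog.
        """
        if not dna or len(dna) % ZF_UNIT_NT != 0:
            raise CatalogError(
                f"array length {len(dna)} is not a positive multiple of {ZF_UNIT_NT}"
            )
        codes: list[str] = []
        for i in range(0, len(dna), ZF_UNIT_NT):
            unit = dna[i : i + ZF_UNIT_NT]
            code = self._dna_to_code.get(unit)
            if code is None:
                zf = ZincFinger(code=self.mint_zf_code(), dna=unit, is_novel=True)
                if register_novel:
                    self.add_finger(zf)
                else:
                    # still validates the unit (length/alphabet/stop codon)
                    pass
                code = zf.code
            codes.append(code)
        return codes


def encode_allele(dna: str, catalog: ZFCatalog, register_novel: bool = True) -> list[str]:
    """Functional form of :meth:`ZFCatalog.encode_allele`."""
    return catalog.encode_allele(dna, register_novel=register_novel)


def name_new_allele(zf_codes: Sequence[str], catalog: ZFCatalog) -> str:
    """Functional form of :meth:`ZFCatalog.name_new_allele`."""
    return catalog.name_new_allele(zf_codes)


# -- file I/O -----------------------------------------------------------

def _looks_like_fasta(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return line.startswith(">")
    return False


def _read_fasta(path: Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def _read_tsv(path: Path, required: Sequence[str]) -> list[dict[str, str]]:
    rows: list[dict[str, str]] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                missing = [c for c in required if c not in header]
                if missing:
                    raise CatalogError(
                        f"{path}:{lineno}: missing column(s) {missing}"
                    )
                continue
            if len(parts) != len(header):
                raise CatalogError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            rows.append(dict(zip(header, parts)))
    if header is None:
        raise CatalogError(f"{path}: empty file")
    return rows


def load_catalog(zf_path: str | Path, allele_path: str | Path | None = None) -> ZFCatalog:
    """Load a catalog from a ZF table/FASTA and an optional allele table/FASTA."""
    zf_path = Path(zf_path)
    catalog = ZFCatalog()
    if _looks_like_fasta(zf_path):
        for code, dna in _read_fasta(zf_path):
            catalog.add_finger(ZincFinger(code=code, dna=dna))
    else:
        for row in _read_tsv(zf_path, ("code", "dna")):
            catalog.add_finger(
                ZincFinger(
                    code=row["code"],
                    dna=row["dna"].upper(),
                    is_novel=row.get("source", "") == "novel",
                )
            )
    if allele_path is None:
        return catalog
    allele_path = Path(allele_path)
    if _looks_like_fasta(allele_path):
        for name, dna in _read_fasta(allele_path):
            codes = catalog.encode_allele(dna, register_novel=True)
            catalog.add_allele(Allele(name=name, zf_codes=codes, dna=dna))
    else:
        for row in _read_tsv(allele_path, ("name", "zf_codes")):
            codes = [c for c in row["zf_codes"].split(",") if c]
            catalog.add_allele(
                Allele(
                    name=row["name"],
                    zf_codes=codes,
                    dna=catalog.build_dna(codes),
                    provenance=row.get("provenance", "population") or "population",
                    type_label=row.get("type_label", "unclassified") or "unclassified",
                )
            )
    return catalog


def save_catalog(
    catalog: ZFCatalog, zf_path: str | Path, allele_path: str | Path | None = None
) -> None:
    """Write the catalog back to the TSV formats read by :func:`load_catalog`."""
    with open(zf_path, "w") as fh:
        fh.write("code\tdna\tsource\n")
        for zf in catalog.fingers.values():
            source = "novel" if zf.is_novel else "published"
            fh.write(f"{zf.code}\t{zf.dna}\t{source}\n")
    if allele_path is None:
        return
    with open(allele_path, "w") as fh:
        fh.write("name\tzf_codes\tprovenance\ttype_label\n")
        for al in catalog.alleles.values():
            fh.write(
                f"{al.name}\t{','.join(al.zf_codes)}\t{al.provenance}\t{al.type_label}\n"
            )
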