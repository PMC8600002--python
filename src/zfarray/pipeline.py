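"""End-to-end convenience: reads → demultiplex → extract → genotype.

Thin orchestration over the extraction and genotyping modules, used by
the CLI, the examples and the evaluation scripts.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .catalog import ZFCatalog
from .extract import BarcodeScheme, FlankAnchors, demultiplex, extract_all
from .genotype import DEFAULT_MIN_COVERAGE, DiploidGenotype, call_genotype
from .simulate import SimulatedCohort


def genotype_reads(
    individual: str,
    reads: Sequence[tuple[str, str]],
    catalog: ZFCatalog,
    anchors: FlankAnchors | None = None,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> DiploidGenotype:
    anchors = anchors or FlankAnchors()
    obs, _ = extract_all(reads, anchors, catalog)
    return call_genotype(individual, obs, catalog, min_coverage=min_coverage)


def genotype_cohort(
    cohort: SimulatedCohort,
    catalog: ZFCatalog,
    anchors: FlankAnchors | None = None,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    through_demux: bool = False,
    scheme: BarcodeScheme | None = None,
) -> dict[str, DiploidGenotype]:
    """Genotype every individual of a simulated cohort.

    With ``through_demux`` the per-individual read sets are pooled and
    re-assigned by barcode first (requires the cohort to have been
    simulated with barcodes), exercising the full pipeline.
    """
    anchors = anchors or FlankAnchors()
    if not through_demux:
        return {
            ind: genotype_reads(ind, reads, catalog, anchors, min_coverage)
            for ind, reads in cohort.reads_by_individual.items()
        }
    scheme = scheme or BarcodeScheme()
    # reconstruct the barcode-pair -> individual map used by the simulator
    inds = sorted(cohort.reads_by_individual)
    pair_of = {ind: (i % 96, (i // 96) % 8) for i, ind in enumerate(inds)}
    ind_of = {pair: ind for ind, pair in pair_of.items()}
    pooled = [r for reads in cohort.reads_by_individual.values() for r in reads]
    demux = demultiplex(pooled, scheme)
    out: dict[str, DiploidGenotype] = {}
    for pair, reads in demux.assigned.items():
        ind = ind_of.get(pair)
        if ind is None:
            continue
        out[ind] = genotype_reads(ind, reads, catalog, anchors, min_coverage)
    for ind in inds:  # individuals losing all reads still get a (failed) call
        if ind not in out:
            out[ind] = genotype_reads(ind, [], catalog, anchors, min_coverage)
    return out


def allele_recovery(
    genotypes: Mapping[str, DiploidGenotype],
    truth: Mapping[str, tuple[str, str]],
) -> float:
    """Fraction of true allele copies recovered exactly (DNA identity,
    multiset comparison per individual)."""
    from collections import Counter

    hit = total = 0
    for ind, pair in truth.items():
        want = Counter(pair)
        got = Counter(genotypes[ind].allele_dnas) if ind in genotypes else Counter()
        hit += sum((want & got).values())
        total += 2
    return hit / total if total else float("nan")
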