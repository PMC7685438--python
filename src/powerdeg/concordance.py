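"""Set-level agreement statistics for DEG lists and enriched-term sets.

Covers four comparisons used when judging reproducibility of weak-effect
differential expression: direction-matched shared DEGs between two analyses,
the expected chance overlap of two direction-signed DEG lists drawn
independently from a common tested universe, the overlap-robustness
proportion between a subsampled and a full enriched-term set, and recovery
counting against a fixed reference term set.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

from .de import DEGSet

__all__ = [
    "OverlapSummary",
    "shared_degs",
    "expected_shared",
    "overlap_robustness",
    "count_recovered_terms",
    "multi_method_consensus",
]


@dataclass(frozen=True)
class OverlapSummary:
    """Sizes and overlap statistics of a two-set comparison."""

    size_a: int
    size_b: int
    observed: int
    expected: float | None = None
    robustness: float | None = None


def shared_degs(a: DEGSet, b: DEGSet) -> DEGSet:
    """Genes significant in both analyses with the same direction.

    Both inputs must use the KO/WT fold-change orientation; a gene counted
    up in one list and down in the other is not shared.
    """
    return DEGSet(
        analysis_id=f"shared({a.analysis_id},{b.analysis_id})",
        members=a.members & b.members,
    )


def expected_shared(G, dA, uA, dB, uB):
    """Expected direction-matched overlap of two independent DEG lists.

    With ``G`` genes tested in both datasets, ``dA``/``uA`` down- and
    up-regulated DEGs in list A and ``dB``/``uB`` in list B, independence
    gives ``((dA/G)(dB/G) + (uA/G)(uB/G)) * G`` expected shared DEGs.
    Returns the real value; round only for presentation.
    """
    G = int(G)
    if G < 1:
        raise ValueError("G must be >= 1")
    for name, val in (("dA", dA), ("uA", uA), ("dB", dB), ("uB", uB)):
        if val < 0:
            raise ValueError(f"{name} must be non-negative")
    if dA + uA > G or dB + uB > G:
        raise ValueError("DEG counts cannot exceed the tested universe G")
    return ((dA / G) * (dB / G) + (uA / G) * (uB / G)) * G


def overlap_robustness(sub_terms, full_terms) -> float:
    """Overlap-robustness proportion P between two enriched-term sets.

    ``P = min(|O| / |sub|, |O| / |full|)`` with ``O`` the intersection.
    Edge rules: both sets empty gives 1.0 (vacuous but complete agreement);
    exactly one empty gives 0.0.  Equals the Jaccard index only when the two
    sets have equal size.
    """
    sub, full = set(sub_terms), set(full_terms)
    if not sub and not full:
        return 1.0
    if not sub or not full:
        return 0.0
    o = len(sub & full)
    return min(o / len(sub), o / len(full))


def count_recovered_terms(enriched_terms, reference_terms) -> int:
    """How many reference terms the enriched set recovers."""
    reference = set(reference_terms)
    if not reference:
        raise ValueError("reference term set must be non-empty")
    return len(set(enriched_terms) & reference)


def multi_method_consensus(degsets) -> DEGSet:
    """Genes significant with the same direction in every input list."""
    degsets = list(degsets)
    if len(degsets) < 2:
        raise ValueError("need at least 2 DEG sets for a consensus")
    return reduce(shared_degs, degsets)
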