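"""Gene-conversion fate model for polyploid clonal lineages.

Gene conversion copies one haplotype (the donor) onto another (the
recipient) over a tract, preserving the total haplotype count.  For a
mutation present on ``c`` of ``p`` haplotypes, one conversion event can
remove a copy, leave the count unchanged, or add a copy — in a triploid
there are exactly six ordered donor/recipient scenarios, two of each fate.
This module enumerates those fates exactly, applies conversions to explicit
haplotype sequences, and classifies the per-site outcomes inside a converted
tract (homozygous LOH, converted-but-heterozygous, or unchanged).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

OUTCOME_ELIMINATED = "eliminated"
OUTCOME_REDUCED = "reduced"
OUTCOME_UNCHANGED = "unchanged"
OUTCOME_EXPANDED = "expanded"

CLASS_LOH = "loh_homozygous"
CLASS_CONVERTED_HET = "converted_heterozygous"
CLASS_UNCHANGED_HET = "unchanged_heterozygous"
CLASS_INVARIANT = "invariant"


@dataclass(frozen=True)
class ConversionScenario:
    """One ordered donor -> recipient conversion and the mutation's fate."""

    donor: int
    recipient: int
    copies_before: int
    copies_after: int
    outcome: str

    def __post_init__(self):
        if self.donor == self.recipient:
            raise ValueError("donor and recipient must differ")


def _outcome(before: int, after: int) -> str:
    if after == before:
        return OUTCOME_UNCHANGED
    if after < before:
        return OUTCOME_ELIMINATED if after == 0 else OUTCOME_REDUCED
    return OUTCOME_EXPANDED


def enumerate_conversion_fates(
    ploidy: int, carrier_copies: int = 1
) -> list[ConversionScenario]:
    """All ``p(p-1)`` ordered conversion scenarios for a single-site variant.

    The variant is carried by ``carrier_copies`` of the ``ploidy`` haplotypes;
    each scenario applies one donor -> recipient conversion to an explicit
    carrier labelling and records the resulting copy number.  A copy count
    that drops to zero is "eliminated"; above its starting value it is
    "expanded" (reaching ``ploidy`` means fixation and full LOH).
    """
    if ploidy < 2:
        raise ValueError("ploidy must be >= 2")
    if not 1 <= carrier_copies <= ploidy:
        raise ValueError(
            f"carrier_copies must be in [1, {ploidy}], got {carrier_copies}")
    # carriers occupy the first `carrier_copies` labelled haplotypes; by
    # exchangeability the tally over ordered pairs does not depend on which
    labels = [np.array([1 if h < carrier_copies else 0], dtype=np.uint8)
              for h in range(ploidy)]
    scenarios = []
    for donor in range(ploidy):
        for recipient in range(ploidy):
            if donor == recipient:
                continue
            after_labels = apply_conversion(labels, donor, recipient, (0, 1))
            after = int(sum(int(a[0]) for a in after_labels))
            scenarios.append(ConversionScenario(
                donor, recipient, carrier_copies, after,
                _outcome(carrier_copies, after)))
    return scenarios


def scenario_tallies(scenarios: Sequence[ConversionScenario]) -> Counter:
    """Outcome -> scenario count."""
    return Counter(s.outcome for s in scenarios)


def apply_conversion(
    haplotypes: Sequence[np.ndarray],
    donor: int,
    recipient: int,
    interval: tuple[int, int],
):
    """Copy the donor haplotype onto the recipient over ``interval``.

    ``haplotypes`` is a sequence of equal-length numpy arrays; the interval
    is 0-based half-open.  Returns a new list of arrays (inputs untouched);
    the haplotype count is conserved and the operation is idempotent.
    """
    p = len(haplotypes)
    if not (0 <= donor < p and 0 <= recipient < p):
        raise IndexError(f"haplotype index out of range for ploidy {p}")
    if donor == recipient:
        raise ValueError("donor and recipient must differ")
    length = haplotypes[0].shape[0]
    start, end = interval
    if not 0 <= start <= end <= length:
        raise ValueError(f"interval [{start}, {end}) outside [0, {length})")
    out = [h.copy() for h in haplotypes]
    out[recipient][start:end] = haplotypes[donor][start:end]
    return out


@dataclass(frozen=True)
class TractSiteClass:
    """Outcome of one tract site under a donor -> recipient conversion."""

    position: int
    site_class: str
    pre: tuple
    post: tuple


def classify_tract_sites(
    haplotypes: Sequence[np.ndarray],
    donor: int,
    recipient: int,
    interval: tuple[int, int],
) -> list[TractSiteClass]:
    """Per-site fates inside a conversion tract, from pre-event haplotypes.

    Site classes partition the tract: non-segregating sites are
    ``invariant``; heterozygous sites where donor and recipient already share
    a base are ``unchanged_heterozygous``; sites driven homozygous (the donor
    base matches every non-participating haplotype) are ``loh_homozygous``;
    the remainder change genotype but stay heterozygous
    (``converted_heterozygous``).
    """
    p = len(haplotypes)
    if not (0 <= donor < p and 0 <= recipient < p) or donor == recipient:
        raise ValueError("invalid donor/recipient")
    start, end = interval
    length = haplotypes[0].shape[0]
    if not 0 <= start <= end <= length:
        raise ValueError(f"interval [{start}, {end}) outside [0, {length})")

    cols = np.stack([h[start:end] for h in haplotypes])  # (p, n)
    n = cols.shape[1]
    seg = (cols != cols[0]).any(axis=0)
    same_dr = cols[donor] == cols[recipient]
    post = cols.copy()
    post[recipient] = cols[donor]
    hom_after = ~(post != post[0]).any(axis=0)

    classes = np.full(n, CLASS_CONVERTED_HET, dtype=object)
    classes[~seg] = CLASS_INVARIANT
    classes[seg & same_dr] = CLASS_UNCHANGED_HET
    classes[seg & ~same_dr & hom_after] = CLASS_LOH

    return [
        TractSiteClass(start + i, classes[i],
                       tuple(int(b) for b in cols[:, i]),
                       tuple(int(b) for b in post[:, i]))
        for i in range(n)
    ]


def expected_homozygous_fraction(
    ploidy: int = 3,
    donor: int = 0,
    recipient: int = 1,
    odd_haplotype: int | None = None,
    mc_draws: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Fraction of heterozygous tract sites driven homozygous by a conversion.

    Site model: bi-allelic sites with exactly one "odd" haplotype, placed
    uniformly (or fixed via ``odd_haplotype``).  The exact fraction is
    obtained by enumerating the odd-haplotype placements as a
    :class:`fractions.Fraction`; with ``mc_draws`` a Monte-Carlo estimate
    over random placements is returned instead (a float).
    """
    if ploidy < 2:
        raise ValueError("ploidy must be >= 2")
    if donor == recipient:
        raise ValueError("donor and recipient must differ")

    def is_loh(odd: int) -> bool:
        col = np.zeros((ploidy, 1), dtype=np.uint8)
        col[odd] = 1
        (site,) = classify_tract_sites(list(col), donor, recipient, (0, 1))
        return site.site_class == CLASS_LOH

    placements = [odd_haplotype] if odd_haplotype is not None else list(range(ploidy))
    if mc_draws is None:
        hits = sum(is_loh(o) for o in placements)
        return Fraction(hits, len(placements))
    if rng is None:
        rng = np.random.default_rng(0)
    draws = rng.choice(placements, size=mc_draws)
    return float(np.mean([is_loh(int(o)) for o in draws]))
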