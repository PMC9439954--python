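"""Core per-site record type shared across the package.

A :class:`SiteRecord` is one variant site observed in one sample: the
chromosome, 1-based position, reference allele, alternative alleles and the
per-allele read depths (reference first).  It is the common currency between
the simulator, the VCF reader and every downstream estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(slots=True)
class SiteRecord:
    """One variant site in one sample.

    Parameters
    ----------
    sample_id : str
        Sample the depths belong to.
    chrom : str
        Chromosome name.
    pos : int
        1-based position, as in VCF.
    ref : str
        Reference allele.
    alts : tuple of str
        Alternative alleles (may be empty for a monomorphic observation at a
        site that is variant in another sample of the cohort).
    depths : tuple of int
        Read depth per allele, ordered (ref, *alts).
    total : int, optional
        Total site depth.  Defaults to ``sum(depths)``; a caller that
        down-sampled alleles may pass a larger value.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    depths: tuple[int, ...]
    total: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if len(self.depths) != 1 + len(self.alts):
            raise ValueError(
                f"{len(self.depths)} depths for {1 + len(self.alts)} alleles "
                f"at {self.chrom}:{self.pos}"
            )
        if any(d < 0 for d in self.depths):
            raise ValueError(f"negative allele depth at {self.chrom}:{self.pos}")
        if self.total < 0:
            self.total = sum(self.depths)
        elif self.total < max(self.depths, default=0):
            raise ValueError(
                f"total depth {self.total} below an allele depth at "
                f"{self.chrom}:{self.pos}"
            )

    # -- depth views -------------------------------------------------------

    @property
    def ref_depth(self) -> int:
        return self.depths[0]

    @property
    def alt_depth(self) -> int:
        """Depth of the deepest alternative allele (0 if none listed)."""
        return max(self.depths[1:], default=0)

    @property
    def both_depth(self) -> int:
        """Depth of reference plus the deepest alternative allele."""
        return self.ref_depth + self.alt_depth

    def two_deepest(self) -> tuple[int, int]:
        """Depths of the two deepest alleles, largest first.

        Multi-allelic sites are reduced to their two deepest alleles for the
        depth-ratio filter and genotype calls; at bi-allelic sites this is
        simply (major, minor).
        """
        top = sorted(self.depths, reverse=True)[:2]
        if len(top) == 1:
            top.append(0)
        return top[0], top[1]

    @property
    def minor_depth(self) -> int:
        return self.two_deepest()[1]

    @property
    def major_allele(self) -> str:
        alleles = (self.ref, *self.alts)
        i = max(range(len(self.depths)), key=lambda j: self.depths[j])
        return alleles[i]

    @property
    def is_segregating(self) -> bool:
        """True if more than one allele has nonzero depth."""
        return sum(1 for d in self.depths if d > 0) > 1
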