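"""Readers and writers for VCF, BED/GFF3 intervals and run artifacts.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based conventions of VCF and GFF3 happens only at these I/O boundaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import pysam
import yaml

from .records import SiteRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")


# ---------------------------------------------------------------------------
# variants


def read_variants(path, samples: Iterable[str] | None = None) -> Iterator[SiteRecord]:
    """Stream SiteRecords from a VCF with per-sample AD fields.

    Records are yielded site by site (sample-major within a site) in file
    order, which must be position-sorted per chromosome.  Sample calls with
    a missing or malformed AD are skipped and counted; a VCF whose header
    lacks the AD FORMAT is rejected outright.
    """
    with pysam.VariantFile(str(path)) as vf:
        if "AD" not in vf.header.formats:
            raise ValueError(f"{path}: VCF header has no AD FORMAT field; "
                             "per-allele depths are required")
        wanted = list(samples) if samples is not None else list(vf.header.samples)
        unknown = set(wanted) - set(vf.header.samples)
        if unknown:
            raise ValueError(f"{path}: unknown samples {sorted(unknown)}")
        n_skipped = 0
        last: dict[str, int] = {}
        seen_order: list[str] = []
        for rec in vf:
            if rec.chrom in last:
                if rec.pos < last[rec.chrom]:
                    raise ValueError(f"{path}: unsorted at {rec.chrom}:{rec.pos}")
                if seen_order[-1] != rec.chrom:
                    raise ValueError(f"{path}: chromosome {rec.chrom} revisited")
            else:
                seen_order.append(rec.chrom)
            last[rec.chrom] = rec.pos
            alts = tuple(a for a in (rec.alts or ()))
            for s in wanted:
                ad = rec.samples[s].get("AD")
                if ad is None or any(d is None for d in ad) \
                        or len(ad) != 1 + len(alts):
                    n_skipped += 1
                    continue
                dp = rec.samples[s].get("DP")
                yield SiteRecord(
                    sample_id=s, chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
                    alts=alts, depths=tuple(int(d) for d in ad),
                    total=int(dp) if dp is not None else -1)
        if n_skipped:
            logger.warning("%s: skipped %d sample calls with missing/malformed AD",
                           path, n_skipped)


def records_by_sample(path, samples=None) -> dict[str, list[SiteRecord]]:
    """Demultiplex :func:`read_variants` into per-sample record lists."""
    out: dict[str, list[SiteRecord]] = {}
    for rec in read_variants(path, samples):
        out.setdefault(rec.sample_id, []).append(rec)
    return out


def write_vcf(
    path,
    records: Mapping[str, list[SiteRecord]],
    contigs: Mapping[str, int],
) -> None:
    """Write per-sample SiteRecords as a multi-sample VCF 4.2 with AD/DP.

    Sites are merged across samples: the allele list at each site is the
    union over samples (reference first) and each sample's depths are
    remapped onto it; a sample without a record at a site is emitted as
    missing.
    """
    sample_ids = list(records)
    # site key -> (ref, [alts...], {sample: {allele: depth}})
    sites: dict[tuple[str, int], tuple[str, list[str], dict]] = {}
    for sid in sample_ids:
        for rec in records[sid]:
            key = (rec.chrom, rec.pos)
            if key not in sites:
                sites[key] = (rec.ref, [], {})
            ref, alts, per_sample = sites[key]
            if rec.ref != ref:
                raise ValueError(f"conflicting REF at {rec.chrom}:{rec.pos}")
            for a in rec.alts:
                if a not in alts:
                    alts.append(a)
            per_sample[sid] = dict(zip((rec.ref, *rec.alts), rec.depths))

    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("AD", "R", "Integer", "Per-allele read depth")
    header.formats.add("DP", "1", "Integer", "Total read depth")
    for sid in sample_ids:
        header.add_sample(sid)

    chrom_rank = {name: i for i, name in enumerate(contigs)}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for (chrom, pos) in sorted(sites, key=lambda k: (chrom_rank[k[0]], k[1])):
            ref, alts, per_sample = sites[(chrom, pos)]
            if not alts:
                continue  # monomorphic across all samples
            alleles = (ref, *alts)
            rec = vf.new_record(contig=chrom, start=pos - 1, alleles=alleles)
            for sid in sample_ids:
                depths = per_sample.get(sid)
                if depths is None:
                    continue
                ad = tuple(depths.get(a, 0) for a in alleles)
                rec.samples[sid]["AD"] = ad
                rec.samples[sid]["DP"] = sum(ad)
            vf.write(rec)


# ---------------------------------------------------------------------------
# intervals


def read_intervals(path, fmt: str | None = None) -> list[Interval]:
    """Read BED (0-based half-open) or GFF3 (1-based inclusive) intervals.

    The format is auto-detected from the extension (override with
    ``fmt="bed"`` or ``"gff3"``); either way the result uses the internal
    0-based half-open convention.  An empty file yields an empty list with
    a warning.
    """
    import pyranges as pr

    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "gff3" if suffix in {".gff", ".gff3"} else "bed"
    if fmt not in {"bed", "gff3"}:
        raise ValueError(f"unknown interval format {fmt!r}")

    if path.stat().st_size == 0 or not any(
            line.strip() and not line.startswith("#")
            for line in path.read_text().splitlines()):
        warnings.warn(f"{path}: empty interval file")
        return []
    try:
        gr = pr.read_bed(str(path)) if fmt == "bed" else pr.read_gff3(str(path))
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise ValueError(f"{path}: failed to parse as {fmt}: {exc}") from exc
    df = gr.df
    out = []
    for i, row in df.iterrows():
        name = "."
        for col in ("Name", "ID", "Feature"):
            if col in df.columns and isinstance(row.get(col), str) and row[col]:
                name = row[col]
                break
        try:
            out.append(Interval(row["Chromosome"], int(row["Start"]),
                                int(row["End"]), name))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: invalid interval on data line {i + 1}: "
                             f"{exc}") from exc
    return out


def write_intervals(path, intervals: Iterable[Interval]) -> None:
    """Write intervals as BED (0-based half-open)."""
    df = pd.DataFrame(
        [(iv.chrom, iv.start, iv.end, iv.name) for iv in intervals],
        columns=["chrom", "start", "end", "name"])
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# run artifacts


def write_truth_tsv(truth, path) -> None:
    """Serialize a simulation truth ledger as TSV (0-based half-open)."""
    truth.to_frame().to_csv(path, sep="\t", index=False)


def write_manifest(out_dir, config: Mapping, seed: int) -> Path:
    """Echo the run configuration, package version and seed to a manifest."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"amphikit_version": __version__, "seed": seed,
                "config": dict(config)}
    path = out_dir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path
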