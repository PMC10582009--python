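"""Standard-format I/O and the in-memory genotype representation.

The pipeline operates on a dense samples x sites matrix of diploid genotype
codes built from a multi-sample VCF: 0 = homozygous reference, 1 =
heterozygous, 2 = homozygous alternate, -1 = missing.  Sites are biallelic
SNPs only; multi-allelic records are dropped on read.  Functional impact
categories follow the SnpEff convention (High / Moderate / Low-Synonymous),
with everything intergenic or intronic relegated to OTHER and excluded from
load accounting downstream.

Coordinate conventions: VCF and GFF3 are 1-based inclusive and are kept that
way internally; BED masks are half-open 0-based and converted on read.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class Impact(IntEnum):
    """Functional impact category of a variant, ordered by severity."""

    UNANNOTATED = 0
    OTHER = 1
    SYNONYMOUS = 2
    MODERATE = 3
    HIGH = 4


_HIGH_TERMS = {
    "stop_gained",
    "splice_donor_variant",
    "splice_acceptor_variant",
    "start_lost",
}
_MODERATE_TERMS = {
    "missense_variant",
    "inframe_insertion",
    "inframe_deletion",
}
_SYNONYMOUS_TERMS = {
    "synonymous_variant",
    "stop_retained_variant",
    "start_retained_variant",
}


def parse_impact(ann_text: str | None) -> Impact:
    """Map a SnpEff-style ANN string to an impact category.

    Accepts a full ANN INFO value (comma-separated entries of
    ``Allele|effect|...`` fields, effects possibly ``&``-joined) or a bare
    effect term.  When several effects annotate one site the most severe
    category wins (HIGH > MODERATE > SYNONYMOUS > OTHER).  An empty or
    missing annotation maps to UNANNOTATED.
    """
    if ann_text is None or not ann_text.strip():
        return Impact.UNANNOTATED
    best = Impact.OTHER
    for entry in ann_text.split(","):
        fields = entry.split("|")
        effect_field = fields[1] if len(fields) > 1 else fields[0]
        for term in effect_field.split("&"):
            term = term.strip().lower()
            if not term:
                continue
            if term in _HIGH_TERMS:
                cat = Impact.HIGH
            elif term in _MODERATE_TERMS:
                cat = Impact.MODERATE
            elif term in _SYNONYMOUS_TERMS:
                cat = Impact.SYNONYMOUS
            else:
                cat = Impact.OTHER
            if cat > best:
                best = cat
    return best


# representative effect term used when writing a matrix back to VCF
_IMPACT_TO_TERM = {
    Impact.HIGH: "stop_gained",
    Impact.MODERATE: "missense_variant",
    Impact.SYNONYMOUS: "synonymous_variant",
    Impact.OTHER: "intergenic_region",
}


@dataclass
class SampleSheet:
    """Sample metadata: id, population/cluster label, sampling year, cohort tag."""

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "population", "year", "cohort")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if self.frame["sample_id"].duplicated().any():
            dups = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        self.frame = self.frame.reset_index(drop=True)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cohort": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def lookup(self, sample_id: str) -> pd.Series:
        rows = self.frame[self.frame["sample_id"] == sample_id]
        if rows.empty:
            raise KeyError(f"sample id not in sample sheet: {sample_id!r}")
        return rows.iloc[0]


@dataclass
class GenomicMask:
    """Sorted, merged half-open 0-based intervals to exclude, per chromosome."""

    intervals: dict[str, np.ndarray]  # (n, 2) int arrays, half-open 0-based
    label: str = "mask"

    def __post_init__(self) -> None:
        self.intervals = {
            c: _merge_intervals(np.asarray(iv, dtype=np.int64).reshape(-1, 2))
            for c, iv in self.intervals.items()
        }

    @classmethod
    def read_bed(cls, path: str | Path, label: str = "mask") -> "GenomicMask":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                s, e = int(start), int(end)
                if e < s:
                    raise ValueError(f"negative-length BED interval: {line!r}")
                by_chrom.setdefault(chrom, []).append((s, e))
        return cls({c: np.array(iv, dtype=np.int64) for c, iv in by_chrom.items()}, label)

    @classmethod
    def empty(cls, label: str = "mask") -> "GenomicMask":
        return cls({}, label)

    def covers(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean array: is each 1-based position inside a masked interval?"""
        pos = np.asarray(pos, dtype=np.int64)
        iv = self.intervals.get(chrom)
        if iv is None or iv.size == 0:
            return np.zeros(pos.shape, dtype=bool)
        # half-open [start, end) covers 1-based p iff start <= p-1 < end
        idx = np.searchsorted(iv[:, 0], pos - 1, side="right") - 1
        ok = idx >= 0
        out = np.zeros(pos.shape, dtype=bool)
        out[ok] = (pos[ok] - 1) < iv[idx[ok], 1]
        return out

    def union(self, other: "GenomicMask") -> "GenomicMask":
        merged: dict[str, np.ndarray] = {}
        for c in set(self.intervals) | set(other.intervals):
            parts = [m.intervals[c] for m in (self, other) if c in m.intervals]
            merged[c] = np.vstack(parts)
        return GenomicMask(merged, f"{self.label}+{other.label}")


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    if iv.size == 0:
        return iv.reshape(0, 2)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


@dataclass
class GeneModel:
    """A gene span from a GFF3 annotation (1-based inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read `gene` features from a GFF3 file as GeneModel records."""
    genes: list[GeneModel] = []
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("gene_id") or f"{cols[0]}:{cols[3]}-{cols[4]}"
            genes.append(GeneModel(gid, cols[0], int(cols[3]), int(cols[4]), cols[6]))
    return genes


def write_gff3_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t.\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


@dataclass
class GenotypeMatrix:
    """Biallelic genotype codes for samples x sites, with per-site metadata.

    genotypes[i, j] is the code of sample i at site j: 0 hom-reference,
    1 heterozygous, 2 hom-alternate, -1 missing.  ``ancestral_is_ref[j]``
    is True when the reference allele is the ancestral (outgroup) allele,
    so the derived-allele dosage at site j is the genotype code itself when
    True and ``2 - code`` when False.
    """

    sample_ids: list[str]
    populations: np.ndarray  # (n_samples,) str
    years: np.ndarray  # (n_samples,) int
    chrom: np.ndarray  # (n_sites,) str
    pos: np.ndarray  # (n_sites,) int64, 1-based
    genotypes: np.ndarray  # (n_samples, n_sites) int8
    ancestral_is_ref: np.ndarray  # (n_sites,) bool
    impact: np.ndarray  # (n_sites,) int8 of Impact values
    ref: np.ndarray | None = None  # (n_sites,) str, optional allele bookkeeping
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=object)
        self.years = np.asarray(self.years, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.ancestral_is_ref = np.asarray(self.ancestral_is_ref, dtype=bool)
        self.impact = np.asarray(self.impact, dtype=np.int8)
        self.validate()

    # -- shape & bookkeeping -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def validate(self) -> None:
        n, m = self.n_samples, self.n_sites
        if self.genotypes.shape != (n, m):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} != ({n}, {m})"
            )
        for name, arr, ln in (
            ("populations", self.populations, n),
            ("years", self.years, n),
            ("chrom", self.chrom, m),
            ("ancestral_is_ref", self.ancestral_is_ref, m),
            ("impact", self.impact, m),
        ):
            if len(arr) != ln:
                raise ValueError(f"{name} has length {len(arr)}, expected {ln}")
        bad = ~np.isin(self.genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes outside {-1,0,1,2}")
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if p.size > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            chrom=self.chrom[index],
            pos=self.pos[index],
            genotypes=self.genotypes[:, index],
            ancestral_is_ref=self.ancestral_is_ref[index],
            impact=self.impact[index],
            ref=None if self.ref is None else self.ref[index],
            alt=None if self.alt is None else self.alt[index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in index],
            populations=self.populations[index],
            years=self.years[index],
            genotypes=self.genotypes[index, :],
        )

    def sample_index(self, population: str | None = None, year: int | None = None) -> np.ndarray:
        keep = np.ones(self.n_samples, dtype=bool)
        if population is not None:
            keep &= self.populations == population
        if year is not None:
            keep &= self.years == year
        return np.flatnonzero(keep)

    def derived_dosage(self) -> np.ndarray:
        """Derived-allele dosage per sample per site; -1 stays missing."""
        d = self.genotypes.astype(np.int8).copy()
        flip = ~self.ancestral_is_ref
        col = d[:, flip]
        col[col >= 0] = 2 - col[col >= 0]
        d[:, flip] = col
        return d


def complete_case_filter(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Retain only sites genotyped in every sample (no missing calls)."""
    keep = ~(gm.genotypes == -1).any(axis=0)
    if keep.all():
        return gm
    return gm.take_sites(np.flatnonzero(keep))


def read_genotypes(
    vcf_path: str | Path,
    sheet: SampleSheet,
    mask: GenomicMask | None = None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a multi-sample VCF.

    Multi-allelic records are dropped; sites falling in ``mask`` are removed;
    the ANN INFO field (if present) is mapped to an impact category, the AA
    INFO field (ancestral allele) orients the derived allele.  Every VCF
    sample must appear in the sample sheet.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    pops, years = [], []
    for s in samples:
        try:
            row = sheet.lookup(s)
        except KeyError as err:
            raise ValueError(str(err)) from None
        pops.append(row["population"])
        years.append(int(row["year"]))

    chrom: list[str] = []
    pos: list[int] = []
    gts: list[np.ndarray] = []
    anc: list[bool] = []
    imp: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        if mask is not None and mask.covers(v.CHROM, np.array([v.POS]))[0]:
            continue
        g = np.asarray(v.gt_types, dtype=np.int8)
        if g.shape[0] != len(samples):
            raise ValueError(
                f"malformed genotype field at {v.CHROM}:{v.POS}"
            )
        g[g == 3] = -1  # cyvcf2 gts012: 3 == unknown
        chrom.append(v.CHROM)
        pos.append(v.POS)
        gts.append(g)
        aa = v.INFO.get("AA")
        anc.append(True if aa is None else str(aa).upper() == str(v.REF).upper())
        imp.append(int(parse_impact(v.INFO.get("ANN"))))
        refs.append(v.REF)
        alts.append(v.ALT[0])
    vcf.close()

    n_sites = len(pos)
    genotypes = (
        np.stack(gts, axis=1) if n_sites else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        sample_ids=samples,
        populations=np.array(pops, dtype=object),
        years=np.array(years, dtype=np.int64),
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        genotypes=genotypes,
        ancestral_is_ref=np.array(anc, dtype=bool),
        impact=np.array(imp, dtype=np.int8),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
    )


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as a plain-text VCFv4.2 file.

    Impact categories are encoded as representative SnpEff effect terms in
    ANN so that reading the file back reproduces them; the ancestral allele
    is recorded in AA.  Round-trips genotypes, positions and impacts exactly.
    """
    ref = gm.ref if gm.ref is not None else np.full(gm.n_sites, "A", dtype=object)
    alt = gm.alt if gm.alt is not None else np.full(gm.n_sites, "T", dtype=object)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in gm.chromosomes():
            end = int(gm.pos[gm.chrom == c].max()) + 1000 if gm.n_sites else 1000
            fh.write(f"##contig=<ID={c},length={end}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotation">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_sites):
            aa = ref[j] if gm.ancestral_is_ref[j] else alt[j]
            info = f"AA={aa}"
            cat = Impact(gm.impact[j])
            if cat != Impact.UNANNOTATED:
                info += f";ANN={alt[j]}|{_IMPACT_TO_TERM[cat]}|x|x"
            row = [
                str(gm.chrom[j]),
                str(gm.pos[j]),
                ".",
                str(ref[j]),
                str(alt[j]),
                ".",
                "PASS",
                info,
                "GT",
            ] + [_GT_STRING[int(g)] for g in gm.genotypes[:, j]]
            fh.write("\t".join(row) + "\n")


def write_table(frame: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    """Write a report table as TSV with '#'-prefixed header lines."""
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# " + "\t".join(map(str, frame.columns)) + "\n")
        frame.to_csv(fh, sep="\t", index=False, header=False)
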