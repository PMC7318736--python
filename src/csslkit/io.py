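"""File I/O for the pipeline's tabular and variant formats.

Interval tables (segments, bins, blocks) are BED-like TSV: 0-based
half-open, sorted by chromosome and start.  SNP genotypes travel as VCF
(via pysam) or as an equivalent coded TSV; marker genotypes, phenotypes and
result tables are plain TSV/CSV with headers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .bin_map import CALL_DONOR, CALL_HET, CALL_MISSING, CALL_RECIPIENT, Bin, SnpTable, filter_alleles
from .genome import GenomeMap
from .qtl_blocks import Block
from .synthetic import MarkerTable

logger = logging.getLogger(__name__)

_CODE_TO_CHAR = {CALL_DONOR: "D", CALL_RECIPIENT: "R", CALL_HET: "H", CALL_MISSING: "N"}
_CHAR_TO_CODE = {v: k for k, v in _CODE_TO_CHAR.items()}


# -- genome table -----------------------------------------------------------

def read_genome_table(path) -> GenomeMap:
    return GenomeMap.from_frame(pd.read_csv(path, sep="\t"))


def write_genome_table(genome: GenomeMap, path) -> None:
    genome.to_frame().to_csv(path, sep="\t", index=False)


# -- SNP tables -------------------------------------------------------------

def write_snp_tsv(table: SnpTable, path) -> None:
    """Coded TSV: chrom, pos, recipient/donor alleles, one D/R/H/N column
    per line."""
    frames = []
    for chrom in table.chroms:
        pos = table.positions[chrom]
        rec, don = (
            table.alleles[chrom]
            if table.alleles is not None and chrom in table.alleles
            else (np.full(len(pos), "A"), np.full(len(pos), "T"))
        )
        df = pd.DataFrame({"chrom": chrom, "pos": pos, "recipient": rec, "donor": don})
        calls = table.calls[chrom]
        for i, line in enumerate(table.lines):
            df[line] = [_CODE_TO_CHAR[int(c)] for c in calls[i]]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_snp_tsv(path) -> SnpTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    lines = tuple(c for c in df.columns if c not in ("chrom", "pos", "recipient", "donor"))
    chroms = tuple(df["chrom"].unique())
    positions, calls, alleles = {}, {}, {}
    for chrom, grp in df.groupby("chrom", sort=False):
        positions[chrom] = grp["pos"].to_numpy(dtype=np.int64)
        alleles[chrom] = (
            grp["recipient"].to_numpy(dtype=object),
            grp["donor"].to_numpy(dtype=object),
        )
        mat = np.empty((len(lines), len(grp)), dtype=np.int8)
        for i, line in enumerate(lines):
            mat[i] = [_CHAR_TO_CODE[c] for c in grp[line]]
        calls[chrom] = mat
    return SnpTable(lines=lines, chroms=chroms, positions=positions, calls=calls, alleles=alleles)


def write_vcf(
    table: SnpTable,
    path,
    genome: GenomeMap | None = None,
    donor_id: str = "donor",
    recipient_id: str = "recipient",
) -> None:
    """Minimal biallelic VCF: REF = recipient allele, ALT = donor allele,
    GT-only, with the two parents as extra samples."""
    header = pysam.VariantHeader()
    header.formats.add("GT", 1, "String", "Genotype")
    for chrom in table.chroms:
        length = genome.bp[chrom] if genome is not None else int(table.positions[chrom][-1]) + 1
        header.contigs.add(chrom, length=length)
    samples = [recipient_id, donor_id, *table.lines]
    for s in samples:
        header.add_sample(s)
    gt_of = {
        CALL_RECIPIENT: (0, 0),
        CALL_DONOR: (1, 1),
        CALL_HET: (0, 1),
        CALL_MISSING: (None, None),
    }
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for chrom in table.chroms:
            pos = table.positions[chrom]
            rec_a, don_a = table.alleles[chrom] if table.alleles else (["A"] * len(pos), ["T"] * len(pos))
            calls = table.calls[chrom]
            for j in range(len(pos)):
                record = vcf.new_record(
                    contig=chrom, start=int(pos[j]), alleles=(str(rec_a[j]), str(don_a[j]))
                )
                record.samples[recipient_id]["GT"] = (0, 0)
                record.samples[donor_id]["GT"] = (1, 1)
                for i, line in enumerate(table.lines):
                    record.samples[line]["GT"] = gt_of[int(calls[i, j])]
                vcf.write(record)


def read_snp_input(path, donor_id: str = "donor", recipient_id: str = "recipient") -> SnpTable:
    """Read a VCF (``.vcf``/``.vcf.gz``) or coded TSV into a SnpTable.

    For VCF: multi-allelic sites, sites where a parent is missing or
    heterozygous, and sites where the parents agree are dropped (counts
    logged).  Line calls are classified against the parental alleles.
    """
    path = Path(path)
    if path.suffix == ".tsv" or path.name.endswith(".tsv.gz"):
        return read_snp_tsv(path)

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for pid in (donor_id, recipient_id):
            if pid not in samples:
                raise KeyError(f"parent sample {pid!r} not in VCF header")
        lines = tuple(s for s in samples if s not in (donor_id, recipient_id))
        positions: dict[str, list[int]] = {}
        calls: dict[str, list[np.ndarray]] = {}
        alleles: dict[str, tuple[list, list]] = {}
        n_multi = n_parent_bad = 0
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_multi += 1
                continue
            gt_d = rec.samples[donor_id].get("GT")
            gt_r = rec.samples[recipient_id].get("GT")
            if not _hom(gt_d) or not _hom(gt_r) or gt_d[0] == gt_r[0]:
                n_parent_bad += 1
                continue
            d_idx, r_idx = gt_d[0], gt_r[0]
            row = np.full(len(lines), CALL_MISSING, dtype=np.int8)
            for i, line in enumerate(lines):
                gt = rec.samples[line].get("GT")
                if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
                    continue
                n_d = (gt[0] == d_idx) + (gt[1] == d_idx)
                n_r = (gt[0] == r_idx) + (gt[1] == r_idx)
                if n_d + n_r == 2:
                    row[i] = (CALL_RECIPIENT, CALL_HET, CALL_DONOR)[n_d]
            chrom = rec.chrom
            positions.setdefault(chrom, []).append(rec.start)
            calls.setdefault(chrom, []).append(row)
            all_alleles = (rec.ref, *rec.alts)
            alleles.setdefault(chrom, ([], []))
            alleles[chrom][0].append(all_alleles[r_idx])
            alleles[chrom][1].append(all_alleles[d_idx])
    if n_multi or n_parent_bad:
        logger.info(
            "dropped %d multi-allelic and %d parent-uninformative sites", n_multi, n_parent_bad
        )
    chroms = tuple(positions)
    return SnpTable(
        lines=lines,
        chroms=chroms,
        positions={c: np.array(positions[c], dtype=np.int64) for c in chroms},
        calls={c: np.column_stack(calls[c]).astype(np.int8) if calls[c] else np.empty((len(lines), 0), np.int8) for c in chroms},
        alleles={c: (np.array(alleles[c][0], dtype=object), np.array(alleles[c][1], dtype=object)) for c in chroms},
    )


def _hom(gt) -> bool:
    return gt is not None and len(gt) == 2 and gt[0] is not None and gt[0] == gt[1]


def read_allele_matrix(path) -> SnpTable:
    """Allele-matrix TSV (chrom, pos, then 'X/Y' base genotypes per sample
    including 'donor' and 'recipient' columns) -> SnpTable via the parental
    allele filter."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["pos"] = df["pos"].astype(np.int64)
    lines = tuple(c for c in df.columns if c not in ("chrom", "pos", "donor", "recipient"))
    positions, calls, alleles = {}, {}, {}
    chroms = tuple(df["chrom"].unique())
    for chrom, grp in df.groupby("chrom", sort=False):
        don = grp["donor"].map(lambda g: g.split("/")[0]).to_numpy(dtype=object)
        rec = grp["recipient"].map(lambda g: g.split("/")[0]).to_numpy(dtype=object)
        geno = grp[list(lines)].to_numpy(dtype=object).T
        keep, coded = filter_alleles(geno, rec, don)
        positions[chrom] = grp["pos"].to_numpy(dtype=np.int64)[keep]
        calls[chrom] = coded
        alleles[chrom] = (rec[keep], don[keep])
    return SnpTable(lines=lines, chroms=chroms, positions=positions, calls=calls, alleles=alleles)


# -- marker tables ----------------------------------------------------------

def write_marker_tsv(table: MarkerTable, path) -> None:
    df = table.markers.copy()
    for line in table.calls.index:
        df[line] = table.calls.loc[line].to_numpy()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_marker_tsv(path) -> MarkerTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    meta_cols = [c for c in ("marker", "chrom", "cm", "bp") if c in df.columns]
    lines = [c for c in df.columns if c not in meta_cols]
    markers = df[meta_cols]
    calls = df[lines].T
    calls.columns = df["marker"]
    calls = calls.where(pd.notna(calls), None)
    return MarkerTable(markers=markers, calls=calls)


# -- interval tables --------------------------------------------------------

def write_bed_like(df: pd.DataFrame, path) -> None:
    """Write a BED-like table sorted by (chrom, start)."""
    df = df.sort_values(["chrom", "start"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def bins_to_frame(bins: list[Bin]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.chrom, b.start, b.end, b.line, b.genotype, b.n_snps) for b in bins],
        columns=["chrom", "start", "end", "line", "genotype", "n_snps"],
    )


# -- phenotypes -------------------------------------------------------------

def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"line", "env", "trait", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"phenotype CSV must have columns {sorted(required)}")
    df["value"] = pd.to_numeric(df["value"])
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# -- manifest ---------------------------------------------------------------

def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, inputs: dict[str, str], params: dict, outputs: dict[str, str]) -> None:
    from . import __version__

    manifest = {
        "version": __version__,
        "inputs": {name: sha256_of(p) for name, p in inputs.items()},
        "params": params,
        "outputs": {name: sha256_of(p) for name, p in outputs.items()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
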