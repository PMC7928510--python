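"""Readers and writers for PLINK-format genotype files and exports.

Supports PED/MAP text files, SNP-major BED/BIM/FAM binary files
(v1.00, magic bytes ``6C 1B 01``), a sample-metadata TSV carrying the
island/herd grouping, and a NEXUS distances export for split-network
viewers.

Genotypes are recoded on read as counts of the minor allele, with the
minor allele determined from the observed frequency (ties broken by
lexicographic allele order), so that downstream MAF filters and
heterozygosity estimates share a consistent reference allele.
"""

from __future__ import annotations

from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MISSING, DatasetError, DistanceMatrixExport, GenotypeDataset

_BED_MAGIC = bytes((0x6C, 0x1B))
_BED_SNP_MAJOR = 0x01

# 2-bit BED code -> allele-A count (A1 = allele_a): 00 hom A1, 01 missing,
# 10 het, 11 hom A2.
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0, MISSING: 1, 1: 2, 0: 3}


class FormatError(ValueError):
    """Raised on malformed PLINK/NEXUS input."""


def _open_text(source):
    if isinstance(source, (str, PathLike)):
        return open(source, "r"), True
    return source, False


def _read_lines(source) -> list[str]:
    handle, owned = _open_text(source)
    try:
        return [ln for ln in (line.strip() for line in handle) if ln]
    finally:
        if owned:
            handle.close()


# ---------------------------------------------------------------------------
# MAP / BIM
# ---------------------------------------------------------------------------

def _parse_map(map_source) -> pd.DataFrame:
    rows = []
    for i, line in enumerate(_read_lines(map_source)):
        fields = line.split()
        if len(fields) < 4:
            raise FormatError(f"MAP line {i + 1}: expected >=4 columns")
        rows.append((fields[0], fields[1], int(fields[3])))
    return pd.DataFrame(rows, columns=["chrom", "snp_id", "pos_bp"])


# ---------------------------------------------------------------------------
# PED/MAP text
# ---------------------------------------------------------------------------

def read_plink_text(
    ped_source,
    map_source,
    metadata: pd.DataFrame | None = None,
    herd_from_family_id: bool = True,
) -> GenotypeDataset:
    """Read a PED/MAP pair into a :class:`GenotypeDataset`.

    The PED family-ID column is mapped to ``herd`` (the only grouping
    field PLINK text files carry); the island label is taken from an
    optional ``metadata`` table (columns ``sample_id``, ``island`` and
    optionally ``herd``) since the format has no second grouping field.

    ``0 0`` allele pairs become missing calls.  SNPs with more than two
    observed alleles raise :class:`FormatError`.
    """
    snp_meta = _parse_map(map_source)
    n_snps = len(snp_meta)

    sample_rows = []
    allele_rows: list[np.ndarray] = []
    for i, line in enumerate(_read_lines(ped_source)):
        fields = line.split()
        if len(fields) != 6 + 2 * n_snps:
            raise FormatError(
                f"PED line {i + 1}: expected {6 + 2 * n_snps} columns "
                f"for {n_snps} MAP SNPs, found {len(fields)}"
            )
        fid, iid = fields[0], fields[1]
        sample_rows.append((iid, fid))
        allele_rows.append(np.array(fields[6:], dtype=object))

    n_samples = len(sample_rows)
    alleles = (
        np.array(allele_rows, dtype=object).reshape(n_samples, n_snps, 2)
        if n_samples
        else np.empty((0, n_snps, 2), dtype=object)
    )

    genotypes = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    allele_a = np.empty(n_snps, dtype=object)
    allele_b = np.empty(n_snps, dtype=object)
    for j in range(n_snps):
        col = alleles[:, j, :]
        called = col != "0"
        observed = sorted(set(col[called].tolist()))
        if len(observed) > 2:
            raise FormatError(
                f"SNP {snp_meta.at[j, 'snp_id']!r} has >2 observed alleles: "
                f"{observed}"
            )
        if not observed:
            observed = ["A", "B"]  # placeholder codes for an all-missing SNP
        if len(observed) == 1:
            # invent a distinct second code for a monomorphic SNP
            other = "B" if observed[0] != "B" else "C"
            observed = observed + [other]
        a1, a2 = observed
        counts1 = (col == a1).sum()
        counts2 = (col == a2).sum()
        # minor allele = less frequent; tie broken lexicographically (a1 < a2)
        minor, major = (a1, a2) if counts1 <= counts2 else (a2, a1)
        allele_a[j], allele_b[j] = minor, major
        ok = called.all(axis=1)
        genotypes[ok, j] = (col[ok] == minor).sum(axis=1)

    samples = pd.DataFrame(sample_rows, columns=["sample_id", "herd"])
    if not herd_from_family_id:
        samples["herd"] = pd.NA
    samples["island"] = pd.NA
    samples = samples[["sample_id", "island", "herd"]]
    snps = snp_meta.assign(allele_a=allele_a, allele_b=allele_b)
    ds = GenotypeDataset(genotypes, samples, snps)
    if metadata is not None:
        ds = attach_sample_metadata(ds, metadata)
    return ds


def write_plink_text(dataset: GenotypeDataset, ped_path, map_path) -> None:
    """Write a dataset as a PED/MAP pair (herd label -> family ID)."""
    with open(map_path, "w") as fh:
        for row in dataset.snps.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos_bp}\n")
    a = dataset.snps["allele_a"].to_numpy(dtype=object)
    b = dataset.snps["allele_b"].to_numpy(dtype=object)
    with open(ped_path, "w") as fh:
        for i, srow in enumerate(dataset.samples.itertuples(index=False)):
            herd = srow.herd if pd.notna(srow.herd) else "0"
            fields = [str(herd), str(srow.sample_id), "0", "0", "0", "-9"]
            g = dataset.genotypes[i]
            for j in range(dataset.n_snps):
                if g[j] == MISSING:
                    fields += ["0", "0"]
                elif g[j] == 2:
                    fields += [a[j], a[j]]
                elif g[j] == 1:
                    fields += [a[j], b[j]]
                else:
                    fields += [b[j], b[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BED/BIM/FAM binary
# ---------------------------------------------------------------------------

def read_plink_binary(
    bed_source, bim_source, fam_source, metadata: pd.DataFrame | None = None
) -> GenotypeDataset:
    """Read a SNP-major BED/BIM/FAM trio into a :class:`GenotypeDataset`.

    A1 in the BIM is taken as allele A (count allele).  Per-SNP blocks
    are 2 bits per sample, LSB first; padding bits in the final byte of
    each block are ignored.
    """
    bim_rows = []
    for i, line in enumerate(_read_lines(bim_source)):
        f = line.split()
        if len(f) < 6:
            raise FormatError(f"BIM line {i + 1}: expected 6 columns")
        bim_rows.append((f[0], f[1], int(f[3]), f[4], f[5]))
    snps = pd.DataFrame(
        bim_rows, columns=["chrom", "snp_id", "pos_bp", "allele_a", "allele_b"]
    )

    fam_rows = []
    for i, line in enumerate(_read_lines(fam_source)):
        f = line.split()
        if len(f) < 2:
            raise FormatError(f"FAM line {i + 1}: expected >=2 columns")
        fam_rows.append((f[1], f[0]))
    samples = pd.DataFrame(fam_rows, columns=["sample_id", "herd"])
    samples["island"] = pd.NA
    samples = samples[["sample_id", "island", "herd"]]

    if isinstance(bed_source, (str, PathLike)):
        raw = Path(bed_source).read_bytes()
    else:
        raw = bed_source.read()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise FormatError("BED file lacks the 6C 1B magic bytes")
    if raw[2] != _BED_SNP_MAJOR:
        raise FormatError("BED mode byte is not 01 (SNP-major)")

    n_samples, n_snps = len(samples), len(snps)
    bytes_per_snp = (n_samples + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if len(body) != bytes_per_snp * n_snps:
        raise FormatError(
            f"BED body has {len(body)} bytes; expected "
            f"{bytes_per_snp * n_snps} for {n_samples} samples x {n_snps} SNPs"
        )
    if n_snps == 0 or n_samples == 0:
        genotypes = np.zeros((n_samples, n_snps), dtype=np.int8)
    else:
        blocks = body.reshape(n_snps, bytes_per_snp)
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        codes = (blocks[:, :, None] >> shifts) & 0x03  # (snp, byte, 4)
        codes = codes.reshape(n_snps, bytes_per_snp * 4)[:, :n_samples]
        genotypes = _BED_DECODE[codes].T.copy()

    ds = GenotypeDataset(genotypes, samples, snps)
    if metadata is not None:
        ds = attach_sample_metadata(ds, metadata)
    return ds


def write_plink_binary(dataset: GenotypeDataset, bed_path, bim_path, fam_path) -> None:
    """Write a dataset as a SNP-major BED/BIM/FAM trio."""
    with open(bim_path, "w") as fh:
        for row in dataset.snps.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.snp_id}\t0\t{row.pos_bp}"
                f"\t{row.allele_a}\t{row.allele_b}\n"
            )
    with open(fam_path, "w") as fh:
        for row in dataset.samples.itertuples(index=False):
            herd = row.herd if pd.notna(row.herd) else "0"
            fh.write(f"{herd} {row.sample_id} 0 0 0 -9\n")

    n_samples, n_snps = dataset.n_samples, dataset.n_snps
    bytes_per_snp = (n_samples + 3) // 4
    # lookup indexed by genotype+1 (missing -1 -> slot 0)
    lut = np.empty(4, dtype=np.uint8)
    lut[0] = _BED_ENCODE[MISSING]
    lut[1] = _BED_ENCODE[0]
    lut[2] = _BED_ENCODE[1]
    lut[3] = _BED_ENCODE[2]
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + bytes((_BED_SNP_MAJOR,)))
        if n_snps and n_samples:
            codes = lut[dataset.genotypes.T.astype(np.int16) + 1]  # (snp, sample)
            padded = np.zeros((n_snps, bytes_per_snp * 4), dtype=np.uint8)
            padded[:, :n_samples] = codes
            padded = padded.reshape(n_snps, bytes_per_snp, 4)
            shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
            packed = (padded << shifts).sum(axis=2).astype(np.uint8)
            fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Sample metadata TSV
# ---------------------------------------------------------------------------

def read_sample_metadata(path) -> pd.DataFrame:
    """Read a sample-metadata TSV (sample_id, island, herd)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "island"}
    if not required.issubset(meta.columns):
        raise FormatError("metadata TSV needs columns sample_id, island[, herd]")
    return meta


def write_sample_metadata(samples: pd.DataFrame, path) -> None:
    samples[["sample_id", "island", "herd"]].to_csv(path, sep="\t", index=False)


def attach_sample_metadata(
    dataset: GenotypeDataset, metadata: pd.DataFrame
) -> GenotypeDataset:
    """Fill island (and optionally herd) labels from a metadata table."""
    meta = metadata.set_index("sample_id")
    missing = [
        s for s in dataset.samples["sample_id"] if s not in meta.index
    ]
    if missing:
        raise FormatError(f"metadata lacks {len(missing)} sample(s): {missing[:5]}")
    samples = dataset.samples.copy()
    samples["island"] = meta.loc[samples["sample_id"], "island"].to_numpy()
    if "herd" in meta.columns:
        samples["herd"] = meta.loc[samples["sample_id"], "herd"].to_numpy()
    return GenotypeDataset(dataset.genotypes.copy(), samples, dataset.snps.copy())


# ---------------------------------------------------------------------------
# NEXUS distances export
# ---------------------------------------------------------------------------

def _nexus_label(label: str) -> str:
    label = str(label)
    if any(ch in label for ch in " \t()[]{}/\\,;:=*'\"`<>^"):
        return "'" + label.replace("'", "''") + "'"
    return label


def export_distance_nexus(dist: DistanceMatrixExport, path) -> None:
    """Write a full square distance matrix as a NEXUS DISTANCES block.

    Output is readable by split-network viewers (e.g. for NeighborNet
    construction, which is left to those tools).
    """
    labels = [_nexus_label(l) for l in dist.labels]
    n = len(labels)
    width = max((len(l) for l in labels), default=1)
    lines = [
        "#NEXUS",
        "",
        "BEGIN TAXA;",
        f"    DIMENSIONS NTAX={n};",
        "    TAXLABELS",
    ]
    lines += [f"        {l}" for l in labels]
    lines += [
        "    ;",
        "END;",
        "",
        "BEGIN DISTANCES;",
        f"    DIMENSIONS NTAX={n};",
        "    FORMAT TRIANGLE=BOTH DIAGONAL LABELS=LEFT;",
        "    MATRIX",
    ]
    for i in range(n):
        row = " ".join(f"{dist.distances[i, j]:.10g}" for j in range(n))
        lines.append(f"        {labels[i]:<{width}} {row}")
    lines += ["    ;", "END;", ""]
    Path(path).write_text("\n".join(lines))
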