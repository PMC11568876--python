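"""Readers and writers for the standard genetic file formats.

Supported formats:

* PLINK binary genotypes (``.bed``/``.bim``/``.fam``) and text genotypes
  (``.ped``/``.map``);
* whitespace-delimited phenotype / covariate tables whose first two columns
  are the family ID and individual ID;
* GCTA binary genetic-relationship-matrix triples
  (``.grm.bin``/``.grm.id``/``.grm.N.bin``).

All sample alignment across sources is by the ``(family_id, individual_id)``
key, never by row position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Variant",
    "GenotypeMatrix",
    "PhenoTable",
    "FormatError",
    "AlignmentError",
    "read_plink_bed",
    "write_plink_bed",
    "read_plink_text",
    "write_plink_text",
    "read_pheno",
    "write_pheno",
    "read_grm_bin",
    "write_grm_bin",
    "impute_mean",
    "align_to",
]

BED_MAGIC = bytes([0x6C, 0x1B])
BED_SNP_MAJOR = 0x01

#: 2-bit PLINK genotype codes -> copies of allele1 (A1).
#: 00 -> hom A1 (2 copies), 10 -> het (1), 11 -> hom A2 (0), 01 -> missing.
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class AlignmentError(ValueError):
    """Two data sources carry inconsistent sample or variant keys."""


class Variant(NamedTuple):
    chrom: str
    id: str
    genetic_pos: float
    bp_pos: int
    allele1: str
    allele2: str


@dataclass
class GenotypeMatrix:
    """n x p allele-count matrix with sample and variant metadata.

    ``dosages[i, k]`` counts copies of ``allele1`` (the bim A1 allele) carried
    by sample ``i`` at variant ``k``; values are in {0, 1, 2} or NaN for
    missing.
    """

    samples: list[tuple[str, str]]
    variants: list[Variant]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, p = self.dosages.shape
        if n != len(self.samples) or n == 0:
            raise ValueError("sample count does not match dosage rows")
        if p != len(self.variants) or p == 0:
            raise ValueError("variant count does not match dosage columns")
        finite = self.dosages[np.isfinite(self.dosages)]
        if not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = list(index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            variants=list(self.variants),
            dosages=self.dosages[index, :].copy(),
        )

    def subset_variants(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = list(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[k] for k in index],
            dosages=self.dosages[:, index].copy(),
        )


@dataclass
class PhenoTable:
    """Keyed phenotype/covariate table.

    ``values`` is an n x c float array; ``missing`` marks entries that carried
    a missing code (-9 or NA by default) in the source file.
    """

    keys: list[tuple[str, str]]
    columns: list[str]
    values: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("need at least one non-key column")
        if len(self.keys) != self.values.shape[0]:
            raise ValueError("key count does not match value rows")
        if len(set(self.keys)) != len(self.keys):
            raise KeyError("duplicate (family_id, individual_id) keys")
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        self.missing = np.asarray(self.missing, dtype=bool)

    def column(self, index: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (values, missing flags) for one column."""
        return self.values[:, index], self.missing[:, index]


def impute_mean(x: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages with the per-variant mean of observed calls."""
    d = x.dosages.copy()
    if np.isnan(d).any():
        col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(d))
        d[idx] = col_mean[idx[1]]
    out = GenotypeMatrix.__new__(GenotypeMatrix)
    out.samples = list(x.samples)
    out.variants = list(x.variants)
    out.dosages = d
    return out


# ---------------------------------------------------------------------------
# PLINK binary
# ---------------------------------------------------------------------------

def _read_fam(path: Path) -> tuple[list[tuple[str, str]], list[list[str]]]:
    rows = [ln.split() for ln in path.read_text().splitlines() if ln.strip()]
    keys = [(r[0], r[1]) for r in rows]
    return keys, rows


def _read_bim(path: Path) -> list[Variant]:
    variants = []
    for ln in path.read_text().splitlines():
        if not ln.strip():
            continue
        f = ln.split()
        variants.append(Variant(f[0], f[1], float(f[2]), int(f[3]), f[4], f[5]))
    return variants


def read_plink_bed(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK binary fileset (``prefix`` + .bed/.bim/.fam).

    The .bed payload must be SNP-major; each variant occupies ceil(n/4)
    bytes, four samples per byte, lowest-order bit pair first.
    """
    prefix = Path(prefix)
    samples, _ = _read_fam(Path(f"{prefix}.fam"))
    variants = _read_bim(Path(f"{prefix}.bim"))
    raw = Path(f"{prefix}.bed").read_bytes()
    if raw[:2] != BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes {raw[:2]!r}")
    if raw[2] != BED_SNP_MAJOR:
        raise FormatError(f"{prefix}.bed: not SNP-major (mode byte {raw[2]:#x})")
    n, p = len(samples), len(variants)
    bytes_per_variant = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_variant * p:
        raise FormatError(
            f"{prefix}.bed: expected {bytes_per_variant * p} data bytes, "
            f"found {payload.size}"
        )
    blocks = payload.reshape(p, bytes_per_variant)
    # expand each byte into its four 2-bit codes, sample-fast
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts) & 0x03  # p x bytes x 4
    codes = codes.reshape(p, bytes_per_variant * 4)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T  # n x p
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def write_plink_bed(x: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a GenotypeMatrix as a PLINK binary fileset (SNP-major)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with Path(f"{prefix}.fam").open("w") as fh:
        for fid, iid in x.samples:
            fh.write(f"{fid} {iid} 0 0 0 -9\n")
    with Path(f"{prefix}.bim").open("w") as fh:
        for v in x.variants:
            fh.write(
                f"{v.chrom}\t{v.id}\t{v.genetic_pos:g}\t{v.bp_pos}"
                f"\t{v.allele1}\t{v.allele2}\n"
            )
    n, p = x.dosages.shape
    # dosage -> 2-bit code (inverse of _CODE_TO_DOSAGE)
    codes = np.full((p, n), 1, dtype=np.uint8)  # missing
    d = x.dosages.T
    codes[d == 2.0] = 0
    codes[d == 1.0] = 2
    codes[d == 0.0] = 3
    bytes_per_variant = (n + 3) // 4
    padded = np.zeros((p, bytes_per_variant * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with Path(f"{prefix}.bed").open("wb") as fh:
        fh.write(BED_MAGIC)
        fh.write(bytes([BED_SNP_MAJOR]))
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------

def read_plink_text(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK text fileset (``prefix`` + .ped/.map).

    The .map file carries no allele columns, so allele1 is inferred per
    variant as the less frequent observed allele (ties broken alphabetically),
    matching PLINK's minor-allele-first convention. "0 0" encodes a missing
    genotype.
    """
    prefix = Path(prefix)
    map_rows = [
        ln.split()
        for ln in Path(f"{prefix}.map").read_text().splitlines()
        if ln.strip()
    ]
    p = len(map_rows)
    samples: list[tuple[str, str]] = []
    alleles: list[list[str]] = []  # per sample: 2p allele tokens
    for ln in Path(f"{prefix}.ped").read_text().splitlines():
        if not ln.strip():
            continue
        f = ln.split()
        samples.append((f[0], f[1]))
        geno = f[6:]
        if len(geno) != 2 * p:
            raise FormatError(
                f"{prefix}.ped: sample {f[1]} has {len(geno)} allele columns, "
                f"expected {2 * p}"
            )
        alleles.append(geno)
    n = len(samples)
    if n == 0:
        raise FormatError(f"{prefix}.ped: no samples")
    dosages = np.full((n, p), np.nan)
    variants: list[Variant] = []
    tokens = np.array(alleles).reshape(n, p, 2)
    for k, row in enumerate(map_rows):
        col = tokens[:, k, :]
        observed = col[col != "0"]
        uniq, counts = np.unique(observed, return_counts=True)
        if uniq.size > 2:
            raise FormatError(f"variant {row[1]}: more than two alleles")
        if uniq.size == 0:
            a1, a2 = "0", "0"
        elif uniq.size == 1:
            # monomorphic: the only observed allele is the major (A2) one
            a1, a2 = "0", str(uniq[0])
        else:
            # minor allele first; alphabetical on ties
            order = np.lexsort((uniq, counts))
            a1, a2 = str(uniq[order[0]]), str(uniq[order[1]])
        missing = (col == "0").any(axis=1)
        dosages[:, k] = np.where(missing, np.nan, (col == a1).sum(axis=1))
        variants.append(
            Variant(row[0], row[1], float(row[2]), int(row[3]), a1, a2)
        )
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def write_plink_text(x: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a GenotypeMatrix as a PLINK text fileset (.ped/.map)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with Path(f"{prefix}.map").open("w") as fh:
        for v in x.variants:
            fh.write(f"{v.chrom}\t{v.id}\t{v.genetic_pos:g}\t{v.bp_pos}\n")
    with Path(f"{prefix}.ped").open("w") as fh:
        for i, (fid, iid) in enumerate(x.samples):
            cols = [fid, iid, "0", "0", "0", "-9"]
            for k, v in enumerate(x.variants):
                d = x.dosages[i, k]
                if np.isnan(d):
                    cols += ["0", "0"]
                elif d == 2:
                    cols += [v.allele1, v.allele1]
                elif d == 1:
                    cols += [v.allele1, v.allele2]
                else:
                    cols += [v.allele2, v.allele2]
            fh.write(" ".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Phenotype / covariate tables
# ---------------------------------------------------------------------------

def read_pheno(
    path: str | Path,
    missing_codes: Sequence[str] = ("-9", "NA"),
) -> PhenoTable:
    """Read a whitespace-delimited phenotype/covariate file.

    The first two columns are the family ID and individual ID; subsequent
    columns are phenotypes or covariates. Rows carrying a missing code are
    retained but flagged, so downstream fits can drop them explicitly.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need >=3 columns (fid iid value...)")
    keys = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    body = df.iloc[:, 2:]
    missing = body.isin(list(missing_codes)).to_numpy()
    values = body.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    missing |= ~np.isfinite(values)
    values = np.where(missing, np.nan, values)
    columns = [f"col{j + 1}" for j in range(values.shape[1])]
    return PhenoTable(keys=keys, columns=columns, values=values, missing=missing)


def write_pheno(
    keys: Sequence[tuple[str, str]],
    values: np.ndarray,
    path: str | Path,
    missing_code: str = "-9",
) -> None:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] != len(keys):
        values = values.T
    with Path(path).open("w") as fh:
        for (fid, iid), row in zip(keys, values):
            cells = [
                missing_code if not np.isfinite(v) else f"{v:.10g}" for v in row
            ]
            fh.write(f"{fid} {iid} " + " ".join(cells) + "\n")


def align_to(
    reference_keys: Sequence[tuple[str, str]],
    table: PhenoTable,
    require_all: bool = False,
) -> tuple[list[int], list[int]]:
    """Align a PhenoTable to a reference key order.

    Returns (reference indices, table row indices) for the intersection,
    ordered by the reference. With ``require_all`` a missing reference key
    raises :class:`AlignmentError`.
    """
    lookup = {k: i for i, k in enumerate(table.keys)}
    ref_idx, tab_idx = [], []
    for i, key in enumerate(reference_keys):
        j = lookup.get(key)
        if j is None:
            if require_all:
                raise AlignmentError(f"sample {key} absent from table")
            continue
        ref_idx.append(i)
        tab_idx.append(j)
    if not ref_idx:
        raise AlignmentError("no overlapping (fid, iid) keys between sources")
    return ref_idx, tab_idx


# ---------------------------------------------------------------------------
# GCTA GRM binary
# ---------------------------------------------------------------------------

def read_grm_bin(prefix: str | Path):
    """Read a GCTA binary GRM (``prefix`` + .grm.bin/.grm.id[/.grm.N.bin]).

    The .grm.bin file packs the lower triangle (i >= j, row-major) in single
    precision. Returns a :class:`kfnet.kernels.KernelMatrix`.
    """
    from .kernels import KernelMatrix  # deferred to avoid an import cycle

    prefix = Path(prefix)
    ids = [
        tuple(ln.split()[:2])
        for ln in Path(f"{prefix}.grm.id").read_text().splitlines()
        if ln.strip()
    ]
    n = len(ids)
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    expected = n * (n + 1) // 2
    if tri.size != expected:
        raise FormatError(
            f"{prefix}.grm.bin: {tri.size} float32 entries, expected {expected}"
        )
    values = np.zeros((n, n))
    il, jl = np.tril_indices(n)
    values[il, jl] = tri
    values[jl, il] = tri
    return KernelMatrix(
        values=values, row_ids=list(ids), col_ids=list(ids), kind="custom",
        params={"source": str(prefix)},
    )


def write_grm_bin(k, prefix: str | Path, n_pairs: float | None = None) -> None:
    """Write a square kernel as a GCTA-compatible GRM triple.

    ``n_pairs`` fills the .grm.N.bin per-pair SNP count (constant); defaults
    to 1 when not given.
    """
    values = np.asarray(k.values, dtype=float)
    if values.shape[0] != values.shape[1] or not np.allclose(
        values, values.T, atol=1e-8
    ):
        raise ValueError("GRM output requires a symmetric square kernel")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    il, jl = np.tril_indices(values.shape[0])
    tri = values[il, jl].astype("<f4")
    tri.tofile(f"{prefix}.grm.bin")
    count = 1.0 if n_pairs is None else float(n_pairs)
    np.full(tri.size, count, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    with Path(f"{prefix}.grm.id").open("w") as fh:
        for fid, iid in k.row_ids:
            fh.write(f"{fid}\t{iid}\n")
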