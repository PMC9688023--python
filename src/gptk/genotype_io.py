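"""Genotype / phenotype containers, standard-format I/O and quality control.

Genotypes are held as an individuals x markers dosage matrix counting copies
of each marker's A1 allele (0, 1, 2; ``NaN`` marks a missing call).  Supported
on-disk formats are the PLINK 1 binary triple (``.bed``/``.bim``/``.fam``,
SNP-major, magic bytes ``0x6C 0x1B 0x01``) and a plain tab-separated dosage
matrix; phenotypes live in a tab-separated table of one id column plus one
column per trait.

Quality control applies, in a fixed order, the filters conventional in
genomic-selection pipelines: per-individual missingness, per-marker call
rate, minor allele frequency, and a 1-df chi-square Hardy-Weinberg
equilibrium test.  Surviving missing dosages are imputed to the marker mean
(``2p``), which is what relationship matrices and kernels downstream expect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigError,
    DataError,
    DimensionError,
    DuplicateIdError,
    EmptyPanelError,
    FormatError,
    UndefinedStatisticError,
    UnknownTraitError,
)

__all__ = [
    "Marker",
    "GenotypeMatrix",
    "PhenotypeTable",
    "QCParams",
    "QCReport",
    "read_plink",
    "write_plink",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_phenotypes",
    "write_phenotypes",
    "allele1_freq",
    "compute_maf",
    "hwe_test",
    "qc_filter",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes, individual-major within each byte (low bits first):
# 00 -> homozygous A1 (dosage 2), 01 -> missing, 10 -> het, 11 -> homozygous A2.
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP record (1-based position, as in a .bim file)."""

    id: str
    chrom: str
    pos: int
    a1: str
    a2: str


@dataclass
class GenotypeMatrix:
    """Individuals x markers A1-dosage matrix with sample and marker metadata.

    ``dosages[i, j]`` counts copies of marker ``j``'s A1 allele carried by
    individual ``i``; missing calls are ``NaN``.  Raw (un-imputed) matrices
    contain only values in {0, 1, 2, NaN}; after quality control the matrix
    is mean-imputed and ``imputed`` is set, so fractional dosages appear.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    markers: list[Marker]
    imputed: bool = False

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.dosages.ndim != 2:
            raise DimensionError("dosage matrix must be 2-D")
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise DimensionError(
                f"{n} dosage rows but {len(self.sample_ids)} sample ids"
            )
        if m != len(self.markers):
            raise DimensionError(f"{m} dosage columns but {len(self.markers)} markers")
        if len(set(self.sample_ids)) != n:
            raise DuplicateIdError("sample ids are not unique")
        if len({mk.id for mk in self.markers}) != m:
            raise DuplicateIdError("marker ids are not unique")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise DataError("dosages must lie in [0, 2]")
        if not self.imputed and finite.size and not np.all(np.isin(finite, (0, 1, 2))):
            raise DataError("un-imputed dosages must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def subset(self, rows=None, cols=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given row / column index arrays."""
        rows = np.arange(self.n_individuals) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_markers) if cols is None else np.asarray(cols)
        return GenotypeMatrix(
            self.dosages[np.ix_(rows, cols)].copy(),
            [self.sample_ids[i] for i in rows],
            [self.markers[j] for j in cols],
            imputed=self.imputed,
        )


@dataclass
class PhenotypeTable:
    """Sample ids plus one or more named trait columns (NaN = missing)."""

    sample_ids: list[str]
    traits: dict[str, np.ndarray]

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DuplicateIdError("phenotype sample ids are not unique")
        self.traits = {k: np.asarray(v, dtype=float) for k, v in self.traits.items()}
        for name, col in self.traits.items():
            if col.shape != (len(self.sample_ids),):
                raise DimensionError(f"trait {name!r} length mismatch")

    def values(self, trait: str) -> np.ndarray:
        if trait not in self.traits:
            raise UnknownTraitError(
                f"unknown trait {trait!r}; available: {sorted(self.traits)}"
            )
        return self.traits[trait]

    def subset(self, rows) -> "PhenotypeTable":
        rows = np.asarray(rows)
        return PhenotypeTable(
            [self.sample_ids[i] for i in rows],
            {k: v[rows].copy() for k, v in self.traits.items()},
        )

    def aligned_to(self, ids: list[str]) -> "PhenotypeTable":
        """Reorder rows to match ``ids`` (alignment is by id, never by row order)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise DataError(f"{len(missing)} ids absent from phenotype table")
        return self.subset([index[s] for s in ids])


@dataclass(frozen=True)
class QCParams:
    """Quality-control thresholds, all fractions/probabilities in [0, 1]."""

    max_missing_per_individual: float = 0.10
    min_maf: float = 0.05
    min_call_rate: float = 0.95
    hwe_p_threshold: float = 1e-6

    def __post_init__(self):
        for name in (
            "max_missing_per_individual",
            "min_maf",
            "min_call_rate",
            "hwe_p_threshold",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"QC parameter {name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Counts of what each filter removed, reconciling with input dimensions."""

    input_dims: tuple[int, int]
    n_individuals_removed: int
    n_markers_removed_by_rule: dict[str, int]
    retained_dims: tuple[int, int]

    def __post_init__(self):
        n_in, m_in = self.input_dims
        n_out, m_out = self.retained_dims
        if n_in - self.n_individuals_removed != n_out:
            raise DataError("QC report individual counts do not reconcile")
        if m_in - sum(self.n_markers_removed_by_rule.values()) != m_out:
            raise DataError("QC report marker counts do not reconcile")


# ---------------------------------------------------------------------------
# PLINK binary triple
# ---------------------------------------------------------------------------

def _byte_decode_table() -> np.ndarray:
    """256 x 4 dosage lookup: byte value -> dosages of its four 2-bit fields."""
    table = np.empty((256, 4))
    for b in range(256):
        for k in range(4):
            table[b, k] = _CODE_TO_DOSAGE[(b >> (2 * k)) & 0b11]
    return table


_DECODE = _byte_decode_table()


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 binary triple ``prefix.bed/.bim/.fam`` (SNP-major)."""
    prefix = Path(prefix)
    bed, bim, fam = (Path(f"{prefix}{s}") for s in (".bed", ".bim", ".fam"))
    for p in (bed, bim, fam):
        if not p.exists():
            raise FormatError(f"missing PLINK file {p}")

    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    sample_ids = fam_df.iloc[:, 1].tolist()
    bim_df = pd.read_csv(bim, sep=r"\s+", header=None, dtype=str)
    markers = [
        Marker(id=r[1], chrom=str(r[0]), pos=int(r[3]), a1=str(r[4]), a2=str(r[5]))
        for r in bim_df.itertuples(index=False)
    ]

    raw = bed.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(
            f"{bed} is not a SNP-major PLINK .bed file (bad magic bytes)"
        )
    n, m = len(sample_ids), len(markers)
    bytes_per_marker = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_marker * m:
        if payload.size < bytes_per_marker * m:
            raise FormatError(f"{bed} is truncated")
        raise DimensionError(
            f"{bed} payload ({payload.size} bytes) does not match "
            f"{n} samples x {m} markers from .fam/.bim"
        )
    # decode per marker: each marker occupies bytes_per_marker bytes
    per_byte = _DECODE[payload.reshape(m, bytes_per_marker)]  # m x bpm x 4
    dosages = per_byte.reshape(m, bytes_per_marker * 4)[:, :n].T.copy()
    return GenotypeMatrix(dosages, sample_ids, markers)


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``g`` as a SNP-major PLINK 1 binary triple."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    d = g.dosages
    finite = d[np.isfinite(d)]
    if finite.size and not np.all(np.isin(finite, (0, 1, 2))):
        raise FormatError("cannot write fractional (imputed) dosages to .bed")

    n, m = d.shape
    bytes_per_marker = (n + 3) // 4
    codes = np.full((m, bytes_per_marker * 4), 0b01, dtype=np.uint8)  # pad=missing
    dt = d.T
    for value, code in _DOSAGE_TO_CODE.items():
        codes[:, :n][dt == value] = code
    codes[:, :n][np.isnan(dt)] = 0b01
    shifted = codes.reshape(m, bytes_per_marker, 4) << np.array([0, 2, 4, 6], np.uint8)
    payload = shifted[..., 0] | shifted[..., 1] | shifted[..., 2] | shifted[..., 3]
    Path(f"{prefix}.bed").write_bytes(_BED_MAGIC + payload.tobytes())

    with Path(f"{prefix}.fam").open("w") as fh:
        for s in g.sample_ids:
            fh.write(f"0\t{s}\t0\t0\t0\t-9\n")
    with Path(f"{prefix}.bim").open("w") as fh:
        for mk in g.markers:
            fh.write(f"{mk.chrom}\t{mk.id}\t0\t{mk.pos}\t{mk.a1}\t{mk.a2}\n")


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

def write_dosage_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Plain dosage matrix: rows = individuals, header = marker ids, NA missing."""
    df = pd.DataFrame(g.dosages, index=g.sample_ids, columns=g.marker_ids)
    df.index.name = "id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    markers = [
        Marker(id=str(c), chrom="0", pos=j + 1, a1="A", a2="B")
        for j, c in enumerate(df.columns)
    ]
    return GenotypeMatrix(df.to_numpy(dtype=float), [str(s) for s in df.index], markers)


def write_phenotypes(y: PhenotypeTable, path: str | Path) -> None:
    df = pd.DataFrame({"id": y.sample_ids, **y.traits})
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str | Path, trait: str | None = None) -> PhenotypeTable:
    """Read a tab-separated phenotype table (id column + trait columns).

    Non-numeric or empty trait cells become missing values, never silently
    dropped rows.  With ``trait`` given, the table is restricted to that one
    column (raising :class:`UnknownTraitError` if absent).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    id_col = df.columns[0]
    ids = df[id_col].tolist()
    if len(set(ids)) != len(ids):
        raise DuplicateIdError(f"duplicate ids in {path}")
    trait_cols = [c for c in df.columns[1:]]
    if trait is not None:
        if trait not in trait_cols:
            raise UnknownTraitError(
                f"trait {trait!r} not in {path}; available: {trait_cols}"
            )
        trait_cols = [trait]
    traits = {
        c: pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
        for c in trait_cols
    }
    return PhenotypeTable(ids, traits)


# ---------------------------------------------------------------------------
# Allele frequencies, HWE, QC
# ---------------------------------------------------------------------------

def allele1_freq(g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Per-marker frequency of the counted (A1) allele among non-missing calls."""
    d = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    n_called = np.sum(np.isfinite(d), axis=0)
    if np.any(n_called == 0):
        raise UndefinedStatisticError(
            "allele frequency undefined for all-missing markers"
        )
    return np.nansum(d, axis=0) / (2.0 * n_called)


def compute_maf(g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Per-marker minor allele frequency ``min(p, 1 - p)``, in [0, 0.5]."""
    p = allele1_freq(g)
    return np.minimum(p, 1.0 - p)


def hwe_test(g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Per-marker Hardy-Weinberg equilibrium p-value.

    1-df chi-square of observed genotype counts against the p^2 / 2pq / q^2
    expectation at the marker's own allele frequency.  Monomorphic markers
    get p = 1 by convention (no deviation is measurable).
    """
    d = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    n_called = np.sum(np.isfinite(d), axis=0)
    if np.any(n_called == 0):
        raise UndefinedStatisticError("HWE test undefined for all-missing markers")
    n_hom1 = np.sum(d == 2, axis=0)
    n_het = np.sum(d == 1, axis=0)
    n_hom2 = np.sum(d == 0, axis=0)
    n = n_hom1 + n_het + n_hom2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n_hom1 + n_het) / (2 * np.maximum(n, 1))
        q = 1.0 - p
        exp = np.stack([n * p**2, 2 * n * p * q, n * q**2])
        obs = np.stack([n_hom1, n_het, n_hom2])
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0).sum(axis=0)
    pvals = stats.chi2.sf(chi2, df=1)
    pvals[(p == 0) | (p == 1) | (n == 0)] = 1.0
    return pvals


def _mean_impute(d: np.ndarray) -> np.ndarray:
    out = d.copy()
    col_mean = np.nanmean(out, axis=0)
    idx = np.where(np.isnan(out))
    out[idx] = col_mean[idx[1]]
    return out


def qc_filter(
    g: GenotypeMatrix, y: PhenotypeTable | None, params: QCParams
) -> tuple[GenotypeMatrix, PhenotypeTable | None, QCReport]:
    """Apply quality control and mean-impute the survivors.

    Filter order is fixed: (1) individuals whose missingness exceeds
    ``max_missing_per_individual``; then markers by (2) call rate,
    (3) MAF (frequencies recomputed after individual removal), (4) HWE.
    The phenotype table, if given, is restricted to the surviving ids.
    """
    n_in, m_in = g.dosages.shape
    miss_frac = np.mean(np.isnan(g.dosages), axis=1)
    keep_ind = np.where(miss_frac <= params.max_missing_per_individual)[0]
    n_removed = n_in - keep_ind.size
    d = g.dosages[keep_ind]

    removed: dict[str, int] = {}
    keep = np.ones(m_in, dtype=bool)
    if keep_ind.size:
        call_rate = np.mean(np.isfinite(d), axis=0)
        fail = call_rate < params.min_call_rate
        removed["call_rate"] = int(fail.sum())
        keep &= ~fail

        maf = np.full(m_in, np.nan)
        called = np.sum(np.isfinite(d), axis=0)
        ok = keep & (called > 0)
        with np.errstate(invalid="ignore"):
            p = np.nansum(d, axis=0) / (2.0 * np.maximum(called, 1))
        maf[ok] = np.minimum(p, 1 - p)[ok]
        fail = keep & ((maf < params.min_maf) | (called == 0))
        removed["maf"] = int(fail.sum())
        keep &= ~fail

        hwe_fail = np.zeros(m_in, dtype=bool)
        if keep.any():
            pvals = hwe_test(d[:, keep])
            hwe_fail[np.where(keep)[0]] = pvals < params.hwe_p_threshold
        removed["hwe"] = int(hwe_fail.sum())
        keep &= ~hwe_fail
    else:
        removed = {"call_rate": 0, "maf": 0, "hwe": 0}
        keep[:] = False

    keep_mk = np.where(keep)[0]
    report = QCReport(
        input_dims=(n_in, m_in),
        n_individuals_removed=n_removed,
        n_markers_removed_by_rule=removed,
        retained_dims=(keep_ind.size, keep_mk.size),
    )
    if keep_ind.size == 0 or keep_mk.size == 0:
        raise EmptyPanelError("no individuals or markers survive QC", report=report)

    out = g.subset(keep_ind, keep_mk)
    out = replace(out, dosages=_mean_impute(out.dosages), imputed=True)
    y_out = y.aligned_to(out.sample_ids) if y is not None else None
    return out, y_out, report
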