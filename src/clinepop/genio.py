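"""Genotype and metadata containers plus readers/writers for the formats the
pipeline consumes: VCF 4.2 (biallelic SNPs, GT field), population-map TSV,
per-population environment TSV, and per-individual trait TSV.

The central container is :class:`GenotypeTable`: an individuals x loci ALT-dosage
matrix (0/1/2, NaN = missing) carrying sample ids, population labels, and locus
coordinates. All genetic stages of the pipeline operate on it.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "GenotypeTable",
    "read_vcf",
    "write_vcf",
    "read_pop_map",
    "write_pop_map",
    "read_env_table",
    "read_trait_table",
]

LOCUS_COLUMNS = ["locus_id", "scaffold", "position", "ref", "alt"]


@dataclasses.dataclass
class GenotypeTable:
    """Individuals x loci dosage matrix with locus coordinates and population labels.

    Parameters
    ----------
    samples : list of str
        Ordered sample ids (rows of ``dosages``).
    populations : dict
        Map sample id -> population id; every sample must be present.
    loci : pandas.DataFrame
        One row per locus with columns ``locus_id, scaffold, position, ref, alt``;
        positions are 1-based as in VCF. Locus ids must be unique.
    dosages : ndarray of float, shape (n_samples, n_loci)
        Count of ALT alleles per call: 0, 1 or 2; NaN marks a missing call.
    """

    samples: list[str]
    populations: dict[str, str]
    loci: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        missing_pop = [s for s in self.samples if s not in self.populations]
        if missing_pop:
            raise ValueError(f"samples without a population label: {missing_pop[:5]}")
        if self.loci["locus_id"].duplicated().any():
            raise ValueError("locus ids are not unique")
        if (self.loci["position"] <= 0).any():
            raise ValueError("locus positions must be positive (1-based)")
        vals = self.dosages[np.isfinite(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")
        self.loci = self.loci.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def pop_labels(self) -> np.ndarray:
        """Population label per sample, aligned with ``samples``."""
        return np.asarray([self.populations[s] for s in self.samples], dtype=object)

    def pop_indices(self) -> dict[str, np.ndarray]:
        """Sample row indices per population, in first-appearance order."""
        labels = self.pop_labels
        out: dict[str, np.ndarray] = {}
        for pop in pd.unique(labels):
            out[pop] = np.flatnonzero(labels == pop)
        return out

    # -- derived statistics ---------------------------------------------
    def alt_freqs(self) -> np.ndarray:
        """Global ALT-allele frequency per locus over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_freqs(self) -> np.ndarray:
        p = self.alt_freqs()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        """Per-locus fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    def observed_het(self) -> np.ndarray:
        """Per-locus observed heterozygosity (fraction of dosage-1 calls)."""
        called = np.isfinite(self.dosages)
        n = called.sum(axis=0).astype(float)
        het = (self.dosages == 1.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, het / n, np.nan)

    # -- subsetting ------------------------------------------------------
    def take_loci(self, index: np.ndarray) -> "GenotypeTable":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeTable(
            samples=self.samples,
            populations=self.populations,
            loci=self.loci.iloc[index].reset_index(drop=True),
            dosages=self.dosages[:, index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeTable":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        samples = [self.samples[i] for i in index]
        return GenotypeTable(
            samples=samples,
            populations={s: self.populations[s] for s in samples},
            loci=self.loci,
            dosages=self.dosages[index, :],
        )

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.samples == other.samples
            and {s: self.populations[s] for s in self.samples}
            == {s: other.populations[s] for s in other.samples}
            and self.loci[LOCUS_COLUMNS].equals(other.loci[LOCUS_COLUMNS])
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    pop_map: dict[str, str] | str | Path | None = None,
    skip_non_biallelic: bool = True,
) -> GenotypeTable | tuple[GenotypeTable, int]:
    """Read a VCF into a :class:`GenotypeTable`.

    Dosage is the count of ALT alleles; ``./.`` becomes NaN. Multiallelic or
    non-SNP records are skipped when ``skip_non_biallelic`` (the count of
    skipped records is available via the two-tuple return when a skip happens),
    otherwise they raise.

    Parameters
    ----------
    pop_map : mapping or path, optional
        sample -> population. When omitted, every sample is put in population
        ``"pop0"`` (callers that need real labels should always pass one).
    """
    path = str(path)
    if pop_map is None:
        populations = None
    elif isinstance(pop_map, (str, Path)):
        populations = read_pop_map(pop_map)
    else:
        populations = dict(pop_map)

    vcf = VCF(path)
    samples = list(vcf.samples)
    if populations is not None:
        absent = [s for s in samples if s not in populations]
        if absent:
            raise ValueError(
                f"samples present in VCF but absent from population map: {absent[:5]}"
            )
    else:
        populations = {s: "pop0" for s in samples}

    rows = []
    dosage_cols = []
    n_skipped = 0
    for i, var in enumerate(vcf):
        is_snp = (
            len(var.REF) == 1
            and len(var.ALT) == 1
            and len(var.ALT[0]) == 1
            and var.ALT[0] in "ACGT"
            and var.REF in "ACGT"
        )
        if not is_snp:
            if skip_non_biallelic:
                n_skipped += 1
                continue
            raise ValueError(
                f"record {i + 1} ({var.CHROM}:{var.POS}) is not a biallelic SNP"
            )
        locus_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        rows.append((locus_id, var.CHROM, int(var.POS), var.REF, var.ALT[0]))
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types.astype(float)
        col = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        dosage_cols.append(col)

    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    dosages = (
        np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    )
    table = GenotypeTable(samples, populations, loci, dosages)
    if n_skipped:
        return table, n_skipped
    return table


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write a GenotypeTable as an uncompressed VCF 4.2 with a GT field.

    Dosage 1 is written ``0/1``, missing as ``./.``; contig headers are emitted
    for every scaffold in locus order of first appearance.
    """
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    lines = [_VCF_HEADER]
    for scaffold in pd.unique(table.loci["scaffold"]):
        lines.append(f"##contig=<ID={scaffold}>\n")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(table.samples)
        + "\n"
    )
    dos = table.dosages
    for j, locus in enumerate(table.loci.itertuples(index=False)):
        gts = "\t".join(
            gt_map.get(dos[i, j], "./.") for i in range(table.n_samples)
        )
        lines.append(
            f"{locus.scaffold}\t{locus.position}\t{locus.locus_id}\t"
            f"{locus.ref}\t{locus.alt}\t.\tPASS\t.\tGT\t{gts}\n"
        )
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# TSV side tables
# ---------------------------------------------------------------------------

def read_pop_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, population) into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "population"} <= set(df.columns):
        raise ValueError("population map must have columns sample_id, population")
    return dict(zip(df["sample_id"], df["population"]))


def write_pop_map(populations: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(populations), "population": list(populations.values())}
    ).to_csv(path, sep="\t", index=False)


def read_env_table(path: str | Path) -> pd.DataFrame:
    """Per-population environment table: population, bio12, salinity, lon, lat."""
    df = pd.read_csv(
        path, sep="\t", dtype={"population": str}, float_precision="round_trip"
    )
    if "population" not in df.columns:
        raise ValueError("environment table must have a 'population' column")
    # integer-looking measurements are still measurements
    for col in df.columns.drop("population"):
        if pd.api.types.is_numeric_dtype(df[col]):
            df[col] = df[col].astype(float)
    return df


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Per-individual trait table: sample_id, population, one column per trait."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "population": str},
        float_precision="round_trip",
    )
    if not {"sample_id", "population"} <= set(df.columns):
        raise ValueError("trait table must have columns sample_id, population")
    for col in df.columns.drop(["sample_id", "population"]):
        if pd.api.types.is_numeric_dtype(df[col]):
            df[col] = df[col].astype(float)
    return df
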