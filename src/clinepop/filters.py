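"""Post-genotyping SNP quality control.

The filter chain applies, in a fixed order, the steps used for reduced-
representation SNP panels genotyped across a handful of small populations:

1. locus call rate across individuals and across sampling locations,
2. excess observed heterozygosity (paralog/merged-locus signal),
3. Hardy-Weinberg disequilibrium in a majority of adequately sampled
   populations (exact test: per-population n here is 2-13, far too small for
   the chi-square approximation),
4. per-locus missingness,
5. global minor-allele frequency.

A :class:`FilterReport` records the locus count before/after each step, in the
style of a per-step retention table. LD pruning (composite genotypic r^2 in a
sliding locus window) lives here too but is applied separately, after outlier
removal, because it serves the PCA/structure stages rather than QC.
"""

from __future__ import annotations

import dataclasses
import json
from functools import lru_cache
from math import lgamma, exp
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import GenotypeTable

__all__ = [
    "FilterConfig",
    "FilterReport",
    "hwe_exact_test",
    "apply_filters",
    "ld_prune",
]


@dataclasses.dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the five-step QC chain.

    Defaults follow the standard reduced-representation workflow: loci kept
    when genotyped in >=80% of individuals and covered in >=80% of the
    sampling locations (a location covers a locus when >=50% of its members
    are called), observed heterozygosity <=0.50, Hardy-Weinberg exact p >=
    0.01 in at least 40% of the populations with >=5 called individuals,
    <=30% missing calls, and global MAF >= 0.05.
    """

    min_ind_call_rate: float = 0.80
    min_loc_fraction: float = 0.80
    loc_cover_rate: float = 0.50
    max_het: float = 0.50
    hwe_alpha: float = 0.01
    hwe_fail_fraction: float = 0.60
    hwe_min_n: int = 5
    max_missing: float = 0.30
    min_maf: float = 0.05
    ld_r2: float = 0.5
    ld_window: int = 50

    def __post_init__(self) -> None:
        for name in (
            "min_ind_call_rate",
            "min_loc_fraction",
            "loc_cover_rate",
            "max_het",
            "hwe_fail_fraction",
            "max_missing",
            "min_maf",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.hwe_alpha < 1.0:
            raise ValueError("hwe_alpha must lie in (0, 1)")


@dataclasses.dataclass
class FilterReport:
    """Ordered per-step accounting: (step name, before, removed, after)."""

    steps: list[tuple[str, int, int, int]] = dataclasses.field(default_factory=list)

    def add(self, name: str, before: int, removed: int) -> None:
        self.steps.append((name, before, removed, before - removed))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["step", "loci_before", "loci_removed", "loci_after"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            [
                {"step": s, "before": b, "removed": r, "after": a}
                for s, b, r, a in self.steps
            ],
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @property
    def final_count(self) -> int:
        return self.steps[-1][3] if self.steps else 0


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=100_000)
def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test of Hardy-Weinberg proportions.

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts and sums the probabilities of all configurations no more
    probable than the observed one. Returns NaN for an empty table; a
    monomorphic table has p = 1 (the observed configuration is the only one).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return float("nan")
    n_a = 2 * n_aa + n_Aa  # minor by convention below
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0

    # log P(het = h | n, rare) up to a shared constant
    def logprob(h: int) -> float:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            h * np.log(2.0)
            - lgamma(hom_rare + 1)
            - lgamma(h + 1)
            - lgamma(hom_common + 1)
        )

    hs = range(rare % 2, rare + 1, 2)
    logs = {h: logprob(h) for h in hs}
    mx = max(logs.values())
    probs = {h: exp(v - mx) for h, v in logs.items()}
    total = sum(probs.values())
    obs = probs[n_Aa]
    # tolerance guards float ties in "no more probable than observed"
    p = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


# ---------------------------------------------------------------------------
# filter chain
# ---------------------------------------------------------------------------

def _genotype_counts_by_pop(table: GenotypeTable):
    """Per population: (n_hom_ref, n_het, n_hom_alt, n_called) arrays per locus."""
    out = {}
    for pop, idx in table.pop_indices().items():
        d = table.dosages[idx]
        out[pop] = (
            (d == 0).sum(axis=0),
            (d == 1).sum(axis=0),
            (d == 2).sum(axis=0),
            np.isfinite(d).sum(axis=0),
        )
    return out


def apply_filters(
    table: GenotypeTable, config: FilterConfig | None = None
) -> tuple[GenotypeTable, FilterReport]:
    """Run the five-step QC chain; returns the filtered table and the report.

    Steps run consecutively, each on the survivors of the previous one, so the
    per-step removal counts depend on the order (kept fixed on purpose).
    """
    config = config or FilterConfig()
    report = FilterReport()
    if table.n_loci == 0:
        for name in ("call_rate", "heterozygosity", "hwe", "missingness", "maf"):
            report.add(name, 0, 0)
        return table, report
    if len(table.pop_indices()) < 1:
        raise ValueError("at least one population is required")

    # step 1: individual call rate + location coverage
    called = np.isfinite(table.dosages)
    ind_call = called.mean(axis=0)
    covers = []
    for pop, idx in table.pop_indices().items():
        if len(idx) == 0:
            continue
        covers.append(called[idx].mean(axis=0) >= config.loc_cover_rate)
    cover_frac = np.vstack(covers).mean(axis=0)
    keep = (ind_call >= config.min_ind_call_rate) & (
        cover_frac >= config.min_loc_fraction
    )
    report.add("call_rate", table.n_loci, int((~keep).sum()))
    table = table.take_loci(keep)

    # step 2: excess observed heterozygosity
    het = table.observed_het()
    keep = ~(het > config.max_het)  # NaN het (no calls) passes; caught later
    report.add("heterozygosity", table.n_loci, int((~keep).sum()))
    table = table.take_loci(keep)

    # step 3: Hardy-Weinberg disequilibrium across populations
    counts = _genotype_counts_by_pop(table)
    n_fail = np.zeros(table.n_loci)
    n_eligible = np.zeros(table.n_loci)
    for pop, (n0, n1, n2, nc) in counts.items():
        eligible = nc >= config.hwe_min_n
        n_eligible += eligible
        for j in np.flatnonzero(eligible):
            p = hwe_exact_test(int(n0[j]), int(n1[j]), int(n2[j]))
            if np.isfinite(p) and p < config.hwe_alpha:
                n_fail[j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        fail_frac = np.where(n_eligible > 0, n_fail / n_eligible, 0.0)
    keep = ~(fail_frac > config.hwe_fail_fraction)
    report.add("hwe", table.n_loci, int((~keep).sum()))
    table = table.take_loci(keep)

    # step 4: per-locus missingness
    keep = ~(table.missing_fraction() > config.max_missing)
    report.add("missingness", table.n_loci, int((~keep).sum()))
    table = table.take_loci(keep)

    # step 5: global minor-allele frequency
    maf = table.minor_allele_freqs()
    keep = ~(maf < config.min_maf)  # NaN maf (no calls) removed explicitly:
    keep &= np.isfinite(maf)
    report.add("maf", table.n_loci, int((~keep).sum()))
    table = table.take_loci(keep)

    return table, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared composite genotypic correlation, pairwise-complete."""
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_prune(
    table: GenotypeTable, r2: float = 0.5, window: int = 50
) -> tuple[GenotypeTable, list[str]]:
    """Greedy LD pruning on composite genotypic r^2 in a sliding locus window.

    Loci are visited in (scaffold, position) order; within a window of
    ``window`` loci, whenever a pair exceeds the r^2 threshold the member with
    the lower global MAF is dropped (ties keep the earlier locus). The result
    is deterministic for a given input order. Unphased dosages only support
    the composite (genotypic) correlation, not gametic r^2.
    """
    if window < 2:
        raise ValueError("ld_window must be at least 2")
    if table.n_loci == 0:
        raise ValueError("cannot prune an empty table")

    order = np.lexsort(
        (table.loci["position"].to_numpy(), table.loci["scaffold"].to_numpy())
    )
    maf = table.minor_allele_freqs()
    scaffold = table.loci["scaffold"].to_numpy()
    dos = table.dosages
    retained: list[int] = []  # positions in `order`-space of kept loci
    removed_mask = np.zeros(table.n_loci, dtype=bool)

    for rank, j in enumerate(order):
        if removed_mask[j]:
            continue
        alive = True
        for rk in reversed(retained):
            i = order[rk]
            if removed_mask[i]:
                continue
            if rank - rk >= window:
                break
            if scaffold[i] != scaffold[j]:
                break
            if _pairwise_r2(dos[:, i], dos[:, j]) > r2:
                if maf[j] > maf[i]:
                    removed_mask[i] = True  # newcomer wins on MAF
                else:
                    removed_mask[j] = True
                    alive = False
                    break
        if alive:
            retained.append(rank)

    removed_ids = table.loci["locus_id"].to_numpy()[removed_mask].tolist()
    return table.take_loci(~removed_mask), removed_ids
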