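"""Cis-QTL mapping of expression traits.

Variants within +/-2 Mb of a gene's strand-aware TSS are QC-filtered
(deduplication, MAF >= 0.05, Hardy-Weinberg exact test at 0.001) and tested
for additive association with a per-individual trait (mean, CV, CV|mean or a
mixture parameter) by simple linear regression on the alternate-allele count.
Family-wise error across the variants of one scan is controlled by max-T
permutations of the trait; Benjamini-Hochberg FDR is computed per trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

MISSING = -1

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "cis_window",
    "hwe_test",
    "filter_variants",
    "additive_scan",
    "genotypic_scan",
    "permutation_fwer",
    "bh_adjust",
    "CisLinkageScan",
    "LinkageResults",
    "run_scan",
]


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError("variant position must be positive (1-based)")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic variants, coded 0/1/2 alt-allele counts, -1 missing."""

    individuals: list[str]
    variants: list[VariantRecord]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.individuals), len(self.variants)):
            raise ValueError("codes shape does not match individuals x variants")
        valid = np.isin(self.codes, [MISSING, 0, 1, 2])
        if not valid.all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            individuals=list(self.individuals),
            variants=[self.variants[i] for i in index],
            codes=self.codes[:, index],
        )

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {ind: i for i, ind in enumerate(self.individuals)}
        missing = [i for i in ids if i not in lookup]
        if missing:
            raise KeyError(f"individuals absent from genotype matrix: {missing}")
        rows = [lookup[i] for i in ids]
        return GenotypeMatrix(
            individuals=list(ids), variants=list(self.variants), codes=self.codes[rows]
        )

    def window(self, chrom: str, interval: tuple[int, int]) -> "GenotypeMatrix":
        lo, hi = interval
        idx = [
            j
            for j, v in enumerate(self.variants)
            if v.chrom == chrom and lo <= v.pos <= hi
        ]
        return self.subset_variants(np.array(idx, dtype=int))

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant over non-missing codes."""
        codes = self.codes
        observed = codes != MISSING
        n_alleles = 2 * observed.sum(axis=0)
        alt = np.where(observed, codes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.divide(alt, n_alleles, out=np.zeros(codes.shape[1]), where=n_alleles > 0)
        return np.minimum(af, 1.0 - af)


def cis_window(tss: int, strand: str = "+", half_width: int = 2_000_000) -> tuple[int, int]:
    """Closed interval of ``half_width`` around the TSS, clamped at position 1.

    The strand decides which transcript endpoint is the TSS (start on '+',
    end on '-'); the caller supplies that coordinate, so the interval itself
    is strand-symmetric.
    """
    if tss <= 0:
        raise ValueError("TSS must be a positive 1-based coordinate")
    if strand not in {"+", "-"}:
        raise ValueError("strand must be '+' or '-'")
    return (max(1, tss - half_width), tss + half_width)


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test on genotype counts.

    Conditions on the allele counts and sums the probabilities of all
    heterozygote counts no more probable than the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no individuals")
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    ok = hom_common >= 0
    hets, hom_rare, hom_common = hets[ok], hom_rare[ok], hom_common[ok]
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def filter_variants(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_alpha: float = 0.001,
    return_log: bool = False,
):
    """Deduplicate, then keep variants with MAF >= ``maf_min`` passing HWE.

    Duplicates share (chrom, pos, ref, alt); the first entry is kept. HWE
    failures are variants whose exact-test p falls below ``hwe_alpha``.
    """
    seen: set = set()
    keep_dedup = []
    for j, v in enumerate(G.variants):
        if v.key in seen:
            continue
        seen.add(v.key)
        keep_dedup.append(j)
    n_dup = G.n_variants - len(keep_dedup)
    G2 = G.subset_variants(np.array(keep_dedup, dtype=int))

    maf = G2.maf()
    keep_maf = maf >= maf_min
    n_maf = int((~keep_maf).sum())

    keep_hwe = np.ones(G2.n_variants, dtype=bool)
    for j in np.flatnonzero(keep_maf):
        codes = G2.codes[:, j]
        codes = codes[codes != MISSING]
        counts = np.bincount(codes, minlength=3)
        if hwe_test(int(counts[0]), int(counts[1]), int(counts[2])) < hwe_alpha:
            keep_hwe[j] = False
    n_hwe = int((keep_maf & ~keep_hwe).sum())

    out = G2.subset_variants(np.flatnonzero(keep_maf & keep_hwe))
    if return_log:
        return out, {"duplicates": n_dup, "maf": n_maf, "hwe": n_hwe}
    return out


def _masked_moments(G: GenotypeMatrix):
    mask = (G.codes != MISSING).astype(float)
    g = np.where(G.codes == MISSING, 0, G.codes).astype(float)
    return g, mask


def _scan_statistics(Y: np.ndarray, g: np.ndarray, mask: np.ndarray):
    """Vectorised per-variant simple regression of each row of Y on genotype.

    ``Y`` is (n_perm_or_1, n_individuals); ``g``/``mask`` are
    (n_individuals, n_variants) with missing genotypes zero-weighted.
    Returns (beta, se, t, n) each of shape (rows, n_variants).
    """
    n = mask.sum(axis=0)  # (V,)
    Sg = (g * mask).sum(axis=0)
    Sgg = (g * g * mask).sum(axis=0)
    Sy = Y @ mask
    Syy = (Y * Y) @ mask
    Sgy = Y @ (g * mask)
    with np.errstate(invalid="ignore", divide="ignore"):
        sxx = Sgg - Sg * Sg / n
        syy = Syy - Sy * Sy / n
        sxy = Sgy - Sg * Sy / n
        beta = sxy / sxx
        resid_ss = np.maximum(syy - beta * sxy, 0.0)
        dof = n - 2
        se = np.sqrt(resid_ss / (dof * sxx))
        t = beta / se
        # a constant trait has beta = 0 with zero residual error: t = 0, not nan
        t = np.where((se == 0) & (beta == 0), 0.0, t)
    bad = (sxx <= 1e-12) | (n < 3)
    beta = np.where(bad, np.nan, beta)
    se = np.where(bad, np.nan, se)
    t = np.where(bad, np.nan, t)
    return beta, se, t, n


def _align_trait(G: GenotypeMatrix, y) -> tuple[GenotypeMatrix, np.ndarray]:
    if isinstance(y, pd.Series):
        ids = [i for i in G.individuals if i in y.index and np.isfinite(y[i])]
        unmatched = [i for i in y.index if i not in set(G.individuals)]
        if not ids:
            raise ValueError(
                f"no overlap between trait and genotype individuals; unmatched: {unmatched}"
            )
        return G.subset_individuals(ids), y.loc[ids].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != G.n_individuals:
        raise ValueError("trait length does not match genotype individuals")
    keep = np.isfinite(y)
    if not keep.all():
        G = GenotypeMatrix(
            individuals=[i for i, k in zip(G.individuals, keep) if k],
            variants=list(G.variants),
            codes=G.codes[keep],
        )
        y = y[keep]
    return G, y


def additive_scan(G: GenotypeMatrix, y) -> pd.DataFrame:
    """Per-variant regression of the trait on alternate-allele count.

    Individuals with missing genotype are dropped variant-wise; returns a
    frame with beta, se, t and the two-sided nominal p on n-2 df.
    """
    G, yv = _align_trait(G, y)
    if G.n_individuals < 10:
        raise ValueError("need >= 10 individuals with genotype and trait")
    g, mask = _masked_moments(G)
    beta, se, t, n = _scan_statistics(yv[None, :], g, mask)
    beta, se, t, n = beta[0], se[0], t[0], n
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    return pd.DataFrame(
        {
            "id": [v.id for v in G.variants],
            "chrom": [v.chrom for v in G.variants],
            "pos": [v.pos for v in G.variants],
            "n": n.astype(int),
            "beta": beta,
            "se": se,
            "t": t,
            "p_nominal": np.where(np.isnan(t), np.nan, p),
        }
    )


def genotypic_scan(G: GenotypeMatrix, y) -> pd.DataFrame:
    """Additive + dominance model: trait ~ allele count + heterozygosity.

    Per variant, a 2-df F test against the intercept-only model. Variants
    without heterozygotes (collinear dominance column) fall back to the
    additive model, flagged in the ``model`` column.
    """
    G, yv = _align_trait(G, y)
    if G.n_individuals < 10:
        raise ValueError("need >= 10 individuals with genotype and trait")
    rows = []
    for j, v in enumerate(G.variants):
        codes = G.codes[:, j]
        ok = codes != MISSING
        gj = codes[ok].astype(float)
        yj = yv[ok]
        n = ok.sum()
        het = (gj == 1).astype(float)
        if n < 4 or np.ptp(gj) == 0:
            rows.append({"id": v.id, "chrom": v.chrom, "pos": v.pos, "n": int(n),
                         "beta_add": np.nan, "beta_dom": np.nan, "F": np.nan,
                         "p_nominal": np.nan, "model": "skipped"})
            continue
        if het.sum() == 0 or np.ptp(het) == 0:
            add = additive_scan(G.subset_variants(np.array([j])), yv)
            rows.append({"id": v.id, "chrom": v.chrom, "pos": v.pos, "n": int(n),
                         "beta_add": add["beta"].iloc[0], "beta_dom": np.nan,
                         "F": np.nan, "p_nominal": add["p_nominal"].iloc[0],
                         "model": "additive_fallback"})
            continue
        X = np.column_stack([np.ones(n), gj, het])
        coef, _, rank, _ = np.linalg.lstsq(X, yj, rcond=None)
        fitted = X @ coef
        sse = float(((yj - fitted) ** 2).sum())
        sst = float(((yj - yj.mean()) ** 2).sum())
        df_num, df_den = 2, n - 3
        if df_den <= 0 or sse <= 0:
            F = np.inf if sst > sse else 0.0
            p = 0.0 if sst > sse else 1.0
        else:
            F = ((sst - sse) / df_num) / (sse / df_den)
            p = float(stats.f.sf(F, df_num, df_den))
        rows.append({"id": v.id, "chrom": v.chrom, "pos": v.pos, "n": int(n),
                     "beta_add": coef[1], "beta_dom": coef[2], "F": F,
                     "p_nominal": p, "model": "genotypic"})
    return pd.DataFrame(rows)


def permutation_fwer(
    G: GenotypeMatrix,
    y,
    observed_t: np.ndarray | None = None,
    n_perm: int = 10000,
    seed: int = 0,
    block_size: int = 512,
) -> np.ndarray:
    """Max-T family-wise corrected p-values over the variants of one scan.

    For each permutation of the trait the maximum |t| across variants is
    recorded; the corrected p of variant v is
    ``(1 + #{perm max |t| >= |t_v|}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    G, yv = _align_trait(G, y)
    g, mask = _masked_moments(G)
    if observed_t is None:
        _, _, t_obs, _ = _scan_statistics(yv[None, :], g, mask)
        observed_t = t_obs[0]
    observed_t = np.asarray(observed_t, dtype=float)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(observed_t.shape, dtype=np.int64)
    abs_obs = np.abs(observed_t)
    done = 0
    while done < n_perm:
        block = min(block_size, n_perm - done)
        Y = np.empty((block, yv.size))
        for b in range(block):
            Y[b] = rng.permutation(yv)
        _, _, t_perm, _ = _scan_statistics(Y, g, mask)
        max_t = np.nanmax(np.abs(t_perm), axis=1)
        # a permutation where every variant is degenerate contributes 0
        max_t = np.where(np.isfinite(max_t), max_t, 0.0)
        exceed += (max_t[:, None] >= abs_obs[None, :] - 1e-12).sum(axis=0)
        done += block
    p_fwer = (1.0 + exceed) / (n_perm + 1.0)
    return np.where(np.isfinite(abs_obs), np.minimum(p_fwer, 1.0), np.nan)


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(list(p), dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


class CisLinkageScan:
    """Model object for one gene x trait cis scan.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        Cohort genotypes; usually already windowed/QC-filtered, otherwise
        pass ``gene=(chrom, tss, strand)`` to :meth:`fit` for windowing.
    trait : pandas.Series
        Per-individual trait values indexed by individual id (or an array
        aligned with ``genotypes.individuals``).
    """

    def __init__(self, genotypes: GenotypeMatrix, trait, name: str = "trait"):
        self.genotypes = genotypes
        self.trait = trait
        self.name = name

    def fit(
        self,
        model: str = "additive",
        n_perm: int = 10000,
        seed: int = 0,
        qc: bool = False,
    ) -> "LinkageResults":
        G = self.genotypes
        if qc:
            G = filter_variants(G)
        if model == "additive":
            table = additive_scan(G, self.trait)
            t_col = table["t"].to_numpy()
        elif model == "genotypic":
            table = genotypic_scan(G, self.trait)
            t_col = None
        else:
            raise ValueError("model must be 'additive' or 'genotypic'")
        if n_perm and model == "additive":
            table["p_fwer"] = permutation_fwer(
                G, self.trait, observed_t=t_col, n_perm=n_perm, seed=seed
            )
        else:
            table["p_fwer"] = np.nan
        table["q_bh"] = bh_adjust(table["p_nominal"])
        return LinkageResults(
            table=table, trait_name=self.name, model=model, n_perm=n_perm, seed=seed
        )


@dataclass
class LinkageResults:
    """Per-variant association results for one scan."""

    table: pd.DataFrame
    trait_name: str
    model: str
    n_perm: int
    seed: int

    @property
    def top(self) -> pd.Series:
        idx = self.table["p_nominal"].idxmin()
        return self.table.loc[idx]

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_fwer"] < alpha]

    def summary(self, n: int = 10) -> pd.DataFrame:
        """Top associations sorted by nominal p."""
        cols = [c for c in ("id", "chrom", "pos", "n", "beta", "se", "t",
                            "p_nominal", "p_fwer", "q_bh") if c in self.table]
        return (
            self.table.sort_values("p_nominal")[cols].head(n).reset_index(drop=True)
        )


def run_scan(
    genotypes: GenotypeMatrix,
    trait_table: pd.DataFrame,
    gene_config: Mapping,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[dict[str, LinkageResults], pd.DataFrame]:
    """Full per-gene scan: window, QC, additive scan, max-T FWER, BH FDR.

    ``trait_table`` is long-form with columns ``individual_id``, ``trait``,
    ``value``; ``gene_config`` needs ``name``, ``chrom``, ``tss``, ``strand``.
    BH FDR is computed within each trait independently. Returns per-trait
    results plus a report with one row per trait (top SNP, corrected p, FDR).
    """
    required = {"individual_id", "trait", "value"}
    if not required.issubset(trait_table.columns):
        raise ValueError(f"trait table needs columns {sorted(required)}")
    window = cis_window(int(gene_config["tss"]), gene_config.get("strand", "+"))
    G = genotypes.window(str(gene_config["chrom"]), window)
    G = filter_variants(G)
    results: dict[str, LinkageResults] = {}
    report_rows = []
    for trait_name, sub in trait_table.groupby("trait"):
        y = pd.Series(
            sub["value"].to_numpy(dtype=float), index=sub["individual_id"].to_numpy()
        )
        shared = [i for i in G.individuals if i in y.index]
        if len(shared) < 10:
            raise ValueError(
                f"trait {trait_name!r}: only {len(shared)} individuals match genotypes"
            )
        model = CisLinkageScan(G.subset_individuals(shared), y.loc[shared], name=trait_name)
        res = model.fit(n_perm=n_perm, seed=seed)
        results[trait_name] = res
        hits = res.significant(alpha)
        top = res.top
        report_rows.append(
            {
                "gene": gene_config["name"],
                "trait": trait_name,
                "n_individuals": len(shared),
                "n_variants": res.table.shape[0],
                "top_snp": top["id"],
                "top_pos": top["pos"],
                "p_fwer": top["p_fwer"],
                "q_bh": top["q_bh"],
                "n_significant": hits.shape[0],
            }
        )
    return results, pd.DataFrame(report_rows)
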