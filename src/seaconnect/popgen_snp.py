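"""Nuclear-SNP population genetics: QC, diversity, HWE/LD, F_ST, IBD, outliers.

The substrate is a biallelic dosage matrix (minor-allele copies 0/1/2,
missing = -1) with locality labels. Differentiation uses the Weir–Cockerham
(1984) variance-component estimator θ with permutation significance;
isolation by distance uses a simple Mantel test; the outlier scan compares
per-locus θ against a locality-label permutation null with
Benjamini–Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .geo import equirectangular_xy_km, haversine_km

__all__ = [
    "GenotypeDataset",
    "PairwiseMatrix",
    "filter_loci",
    "exclude_failed_samples",
    "diversity",
    "hwe_exact",
    "hwe_exact_pvalue",
    "ld_pairwise",
    "fisher_exact_rxc",
    "fst_wc",
    "fst_pairwise_matrix",
    "fst_standardised",
    "standardised_fst_transect",
    "geographic_distance_matrix",
    "ibd_mantel",
    "outlier_scan",
]

MISSING = -1


@dataclass
class GenotypeDataset:
    """Individuals × biallelic loci as minor-allele dosage with locality labels."""

    ind_ids: list
    localities: np.ndarray
    locus_ids: list
    dosage: np.ndarray  # (n_ind, n_loci) int8; -1 = missing
    locus_meta: pd.DataFrame | None = None  # call_rate, maf, reproducibility

    def __post_init__(self):
        self.localities = np.asarray(self.localities, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.ind_ids), len(self.locus_ids)):
            raise ValueError("dosage shape must be (n_individuals, n_loci)")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2,-1}")
        if self.locus_meta is None:
            self.locus_meta = pd.DataFrame(index=pd.Index(self.locus_ids, name="locus"))
        if "reproducibility" not in self.locus_meta:
            self.locus_meta["reproducibility"] = 1.0
        self._refresh_meta()

    def _refresh_meta(self):
        self.locus_meta = self.locus_meta.loc[self.locus_ids].copy()
        self.locus_meta["call_rate"] = self.call_rates()
        self.locus_meta["maf"] = self.mafs()

    @property
    def n_ind(self) -> int:
        return len(self.ind_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def pops(self) -> list:
        seen = {}
        for x in self.localities:
            seen.setdefault(x, None)
        return list(seen)

    def call_rates(self) -> np.ndarray:
        return 1.0 - np.mean(self.dosage == MISSING, axis=0)

    def mafs(self) -> np.ndarray:
        """Pooled minor-allele frequency per locus over non-missing calls."""
        ok = self.dosage != MISSING
        n2 = 2.0 * ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.where(ok, self.dosage, 0).sum(axis=0) / np.where(n2 > 0, n2, np.nan)
        return np.fmin(p, 1.0 - p)

    def subset(self, ind_mask=None, locus_mask=None) -> "GenotypeDataset":
        im = np.ones(self.n_ind, bool) if ind_mask is None else np.asarray(ind_mask, bool)
        lm = np.ones(self.n_loci, bool) if locus_mask is None else np.asarray(locus_mask, bool)
        return GenotypeDataset(
            ind_ids=[i for i, keep in zip(self.ind_ids, im) if keep],
            localities=self.localities[im],
            locus_ids=[l for l, keep in zip(self.locus_ids, lm) if keep],
            dosage=self.dosage[np.ix_(im, lm)],
            locus_meta=self.locus_meta.loc[np.asarray(self.locus_ids, dtype=object)[lm]],
        )

    # ---- text I/O: dosage TSV and minimal GT-only VCF ----
    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosage, columns=self.locus_ids)
        df = df.mask(df == MISSING)
        head = pd.DataFrame({"individual": self.ind_ids, "locality": self.localities})
        pd.concat([head, df], axis=1).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeDataset":
        df = pd.read_csv(path, sep="\t")
        loci = [c for c in df.columns if c not in ("individual", "locality")]
        dosage = df[loci].fillna(MISSING).to_numpy(dtype=np.int8)
        return cls(
            ind_ids=df["individual"].astype(str).tolist(),
            localities=df["locality"].to_numpy(dtype=object),
            locus_ids=loci,
            dosage=dosage,
        )

    def to_vcf(self, path) -> None:
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("##contig=<ID=1>\n")
            for pop in self.pops:
                n = int(np.sum(self.localities == pop))
                fh.write(f"##locality=<ID={pop},N={n}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(self.ind_ids) + "\n")
            for j, locus in enumerate(self.locus_ids):
                gts = "\t".join(gt_map[int(g)] for g in self.dosage[:, j])
                fh.write(f"1\t{j + 1}\t{locus}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")

    @classmethod
    def from_vcf(cls, path, localities: dict | None = None) -> "GenotypeDataset":
        """Read a minimal GT-only VCF (the dialect this package writes).

        ``localities`` maps individual id → locality; if omitted, labels are
        recovered from the ``##locality`` header lines when present.
        """
        ind_ids, loci, rows = [], [], []
        header_loc = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("##locality=<ID="):
                    inner = line[len("##locality=<") : -1]
                    kv = dict(p.split("=", 1) for p in inner.split(","))
                    header_loc[kv["ID"]] = int(kv["N"])
                    continue
                if line.startswith("##"):
                    continue
                if line.startswith("#CHROM"):
                    ind_ids = line.split("\t")[9:]
                    continue
                parts = line.split("\t")
                loci.append(parts[2])
                row = []
                for gt in parts[9:]:
                    gt = gt.split(":")[0]
                    alleles = gt.replace("|", "/").split("/")
                    if "." in alleles:
                        row.append(MISSING)
                    else:
                        row.append(sum(int(a) for a in alleles))
                rows.append(row)
        dosage = np.array(rows, dtype=np.int8).T
        if localities is not None:
            labels = np.array([localities[i] for i in ind_ids], dtype=object)
        elif header_loc and sum(header_loc.values()) == len(ind_ids):
            labels = np.array([p for p, n in header_loc.items() for _ in range(n)], dtype=object)
        else:
            labels = np.array(["pop1"] * len(ind_ids), dtype=object)
        return cls(ind_ids=ind_ids, localities=labels, locus_ids=loci, dosage=dosage)


@dataclass
class PairwiseMatrix:
    """Symmetric zero-diagonal matrix over ordered locality labels."""

    labels: list
    values: np.ndarray
    pvalues: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


# ---------------------------------------------------------------- filtering

def filter_loci(
    gd: GenotypeDataset,
    min_call_rate: float = 0.95,
    min_maf: float = 0.05,
    min_reproducibility: float | None = None,
):
    """Sequential locus QC: call rate → MAF → reproducibility.

    Returns the filtered dataset and per-criterion removal counts. MAF is the
    pooled minor-allele frequency over all non-missing calls. Loci must be
    strictly above the call-rate and MAF thresholds to survive.
    """
    for thr in (min_call_rate, min_maf):
        if not (0.0 <= thr <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")
    counts = {}
    keep = gd.call_rates() > min_call_rate
    counts["call_rate"] = int(np.sum(~keep))
    step = gd.subset(locus_mask=keep)

    keep = step.mafs() > min_maf
    counts["maf"] = int(np.sum(~keep))
    step = step.subset(locus_mask=keep)

    if min_reproducibility is not None:
        rep = step.locus_meta["reproducibility"].to_numpy(dtype=float)
        keep = rep >= min_reproducibility
        counts["reproducibility"] = int(np.sum(~keep))
        step = step.subset(locus_mask=keep)
    else:
        counts["reproducibility"] = 0
    counts["retained"] = step.n_loci
    if step.n_loci == 0:
        warnings.warn("all loci removed by QC filters", stacklevel=2)
    return step, counts


def exclude_failed_samples(gd: GenotypeDataset, max_missing_per_ind: float = 0.5):
    """Drop individuals whose missing-call fraction exceeds the threshold."""
    if not (0.0 <= max_missing_per_ind <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    miss = np.mean(gd.dosage == MISSING, axis=1)
    keep = miss <= max_missing_per_ind
    out = gd.subset(ind_mask=keep)
    sizes = pd.Series(out.localities).value_counts().to_dict()
    return out, sizes


# ---------------------------------------------------------------- diversity

def _rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Hurlbert rarefaction: expected allele count in a sample of g gene copies."""
    N = counts.sum()
    if g > N:
        return np.nan
    terms = []
    for Ni in counts:
        if Ni == 0:
            continue
        if N - Ni < g:
            terms.append(1.0)
        else:
            logp = (gammaln(N - Ni + 1) - gammaln(g + 1) - gammaln(N - Ni - g + 1)) - (
                gammaln(N + 1) - gammaln(g + 1) - gammaln(N - g + 1)
            )
            terms.append(1.0 - np.exp(logp))
    return float(np.sum(terms))


def diversity(gd: GenotypeDataset, rarefaction_g: int | None = None) -> pd.DataFrame:
    """Per-locality diversity: Na, rarefied Ar, Ho, unbiased He, polymorphic fraction.

    He uses the 2n/(2n−1) small-sample correction; Ar uses hypergeometric
    rarefaction at ``rarefaction_g`` gene copies (default: smallest locality's
    minimum non-missing allele count). Loci with fewer copies than g in a
    locality are skipped for Ar there.
    """
    rows = []
    pops = gd.pops
    if rarefaction_g is None:
        gmin = np.inf
        for pop in pops:
            sub = gd.dosage[gd.localities == pop]
            n_ok = 2 * np.sum(sub != MISSING, axis=0)
            if n_ok.size:
                gmin = min(gmin, int(n_ok.min()))
        rarefaction_g = max(int(gmin), 2) if np.isfinite(gmin) else 2
    for pop in pops:
        sub = gd.dosage[gd.localities == pop]
        ok = sub != MISSING
        n_ind = ok.sum(axis=0).astype(float)
        n2 = 2.0 * n_ind
        alt = np.where(ok, sub, 0).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / n2
        valid = n2 > 0
        na = np.where((p > 0) & (p < 1), 2.0, 1.0)
        ho = np.where(ok, sub == 1, False).sum(axis=0) / np.where(n_ind > 0, n_ind, np.nan)
        he_raw = 2.0 * p * (1.0 - p)
        with np.errstate(invalid="ignore", divide="ignore"):
            he = np.where(n2 > 1, n2 / (n2 - 1.0) * he_raw, np.nan)
        ar = []
        for j in range(gd.n_loci):
            if not valid[j] or n2[j] < rarefaction_g:
                continue
            cnt = np.array([n2[j] - alt[j], alt[j]])
            ar.append(_rarefied_richness(cnt, rarefaction_g))
        rows.append(
            {
                "locality": pop,
                "n": int(np.sum(gd.localities == pop)),
                "Na": float(np.nanmean(np.where(valid, na, np.nan))),
                "Ar": float(np.mean(ar)) if ar else np.nan,
                "Ho": float(np.nanmean(ho)),
                "He": float(np.nanmean(he)),
                "polymorphic_fraction": float(np.nanmean(np.where(valid, (p > 0) & (p < 1), np.nan))),
            }
        )
    return pd.DataFrame(rows).set_index("locality")


# ---------------------------------------------------------------- HWE exact

def _hwe_het_distribution(n: int, n_minor: int):
    """Exact conditional distribution of heterozygote count given allele counts.

    n is the diploid sample size and n_minor the minor-allele copy count
    (0..n). Returns (het_values, probabilities).
    """
    n_total = 2 * n
    n_major = n_total - n_minor
    hmin = n_minor % 2
    hmax = min(n_minor, n_major)
    hs = np.arange(hmin, hmax + 1, 2)
    n_aa = (n_minor - hs) // 2
    n_AA = n - n_aa - hs
    logp = (
        gammaln(n + 1)
        - gammaln(n_AA + 1)
        - gammaln(hs + 1)
        - gammaln(n_aa + 1)
        + hs * np.log(2.0)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return hs, p


def hwe_exact_pvalue(n_hom_major: int, n_het: int, n_hom_minor: int):
    """Exact HWE test on genotype counts.

    Returns (p_two_sided, p_deficit) where the two-sided p sums the
    probabilities of all heterozygote configurations no more probable than
    the observed one, and p_deficit is the one-sided probability of observing
    at most the observed heterozygote count.
    """
    n = n_hom_major + n_het + n_hom_minor
    if n < 2:
        return np.nan, np.nan
    n_minor = n_het + 2 * n_hom_minor
    n_minor = min(n_minor, 2 * n - n_minor)
    hs, probs = _hwe_het_distribution(n, n_minor)
    obs = n_het
    if obs not in hs:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    p_obs = probs[hs == obs][0]
    p_two = float(np.sum(probs[probs <= p_obs * (1 + 1e-12)]))
    p_def = float(np.sum(probs[hs <= obs]))
    return min(p_two, 1.0), min(p_def, 1.0)


def hwe_exact(gd: GenotypeDataset, per_locality: bool = True, alpha: float = 0.05) -> pd.DataFrame:
    """Exact HWE tests per (locus, locality); flags heterozygote deficiency.

    A locus/locality cell is flagged deficient when the observed heterozygote
    fraction is below Hardy–Weinberg expectation and the one-sided deficiency
    p-value is below ``alpha``.
    """
    groups = gd.pops if per_locality else ["__pooled__"]
    rows = []
    for pop in groups:
        sub = gd.dosage if pop == "__pooled__" else gd.dosage[gd.localities == pop]
        for j, locus in enumerate(gd.locus_ids):
            col = sub[:, j]
            col = col[col != MISSING]
            if col.size < 2:
                rows.append({"locus": locus, "locality": pop, "p": np.nan, "p_deficit": np.nan, "het_deficient": False})
                continue
            n0 = int(np.sum(col == 0))
            n1 = int(np.sum(col == 1))
            n2c = int(np.sum(col == 2))
            p_two, p_def = hwe_exact_pvalue(n0, n1, n2c)
            n = col.size
            q = (n1 + 2 * n2c) / (2.0 * n)
            exp_het = 2.0 * q * (1.0 - q)
            deficient = (n1 / n) < exp_het and p_def < alpha
            rows.append({"locus": locus, "locality": pop, "p": p_two, "p_deficit": p_def, "het_deficient": bool(deficient)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- LD exact

def fisher_exact_rxc(table: np.ndarray, rng: np.random.Generator | None = None, max_tables: int = 200000, n_mc: int = 2000) -> float:
    """Exact conditional (Fisher–Freeman–Halton) p-value for an r×c table.

    Enumerates all tables with the observed margins when feasible, summing
    the multivariate hypergeometric probabilities of tables no more probable
    than the observed one; falls back to seeded Monte Carlo sampling of the
    null (random pairing with fixed margins) for large problems.
    """
    t = np.asarray(table, dtype=int)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.size == 0 or min(t.shape) < 2:
        return 1.0
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())
    log_denom = gammaln(n + 1) - np.sum(gammaln(rows + 1)) - np.sum(gammaln(cols + 1))

    def log_prob(tab):
        return -log_denom - np.sum(gammaln(np.asarray(tab) + 1))

    lp_obs = log_prob(t)
    # rough enumeration size bound: product of per-cell ranges of the free block
    est = 1.0
    for i in range(len(rows) - 1):
        for j in range(len(cols) - 1):
            est *= min(rows[i], cols[j]) + 1
            if est > max_tables:
                break
        if est > max_tables:
            break
    if est <= max_tables:
        total = 0.0
        r, c = len(rows), len(cols)

        def recurse(i, row_rem, col_rem, acc):
            nonlocal total
            if i == r - 1:
                last = col_rem
                if np.any(last < 0):
                    return
                lp = acc - np.sum(gammaln(last + 1))
                if lp <= lp_obs + 1e-12:
                    total += np.exp(lp)
                return
            _fill_row(i, 0, row_rem, col_rem.copy(), rows[i], acc, recurse)

        def _fill_row(i, j, row_rem, col_rem, rem, acc, cont):
            if j == c - 1:
                if rem > col_rem[j]:
                    return
                col_rem[j] -= rem
                cont(i + 1, row_rem, col_rem, acc - gammaln(rem + 1))
                col_rem[j] += rem
                return
            for x in range(min(rem, col_rem[j]) + 1):
                col_rem[j] -= x
                _fill_row(i, j + 1, row_rem, col_rem, rem - x, acc - gammaln(x + 1), cont)
                col_rem[j] += x

        recurse(0, rows.copy(), cols.copy(), -log_denom)
        return float(min(total, 1.0))
    # Monte Carlo fallback: permute one margin
    rng = np.random.default_rng() if rng is None else rng
    a = np.repeat(np.arange(len(rows)), rows)
    b = np.repeat(np.arange(len(cols)), cols)
    count = 0
    for _ in range(n_mc):
        perm = rng.permutation(b)
        tab = np.zeros_like(t)
        np.add.at(tab, (a, perm), 1)
        if log_prob(tab) <= lp_obs + 1e-12:
            count += 1
    return (1 + count) / (1 + n_mc)


def ld_pairwise(
    gd: GenotypeDataset,
    pairs: list | None = None,
    max_pairs: int = 500,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genotypic LD: exact test on the 3×3 genotype table per locus pair and locality.

    ``pairs`` is a list of (locus_id, locus_id); if omitted, up to
    ``max_pairs`` random pairs are drawn (seeded). Monomorphic or degenerate
    tables give p = 1.
    """
    rng = np.random.default_rng(seed)
    lid = {l: j for j, l in enumerate(gd.locus_ids)}
    if pairs is None:
        npair = gd.n_loci * (gd.n_loci - 1) // 2
        want = min(max_pairs, npair)
        chosen = set()
        while len(chosen) < want:
            a, b = rng.integers(0, gd.n_loci, size=2)
            if a != b:
                chosen.add((min(a, b), max(a, b)))
        pairs = [(gd.locus_ids[a], gd.locus_ids[b]) for a, b in sorted(chosen)]
    rows = []
    for la, lb in pairs:
        ja, jb = lid[la], lid[lb]
        for pop in gd.pops:
            sub = gd.dosage[gd.localities == pop]
            a, b = sub[:, ja], sub[:, jb]
            ok = (a != MISSING) & (b != MISSING)
            a, b = a[ok], b[ok]
            tab = np.zeros((3, 3), dtype=int)
            np.add.at(tab, (a, b), 1)
            p = fisher_exact_rxc(tab, rng=rng)
            rows.append({"locus_a": la, "locus_b": lb, "locality": pop, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["significant"] = out["p"] < alpha
        out.attrs["n_significant"] = int(out["significant"].sum())
        out.attrs["bh_significant"] = int(multipletests(out["p"].to_numpy(), alpha=alpha, method="fdr_bh")[0].sum())
    return out


# ---------------------------------------------------------------- F_ST

def _wc_components(dosage: np.ndarray, labels: np.ndarray, pops: list):
    """Weir–Cockerham per-locus variance components (a, b, c) for r populations.

    Missing dosage is handled complete-case per locus. Returns arrays of
    shape (n_loci,) and a validity mask (polymorphic, estimable loci).
    """
    r = len(pops)
    n_loci = dosage.shape[1]
    n_i = np.zeros((r, n_loci))
    p_i = np.zeros((r, n_loci))
    h_i = np.zeros((r, n_loci))
    for k, pop in enumerate(pops):
        sub = dosage[labels == pop]
        ok = sub != MISSING
        n = ok.sum(axis=0).astype(float)
        alt = np.where(ok, sub, 0).sum(axis=0).astype(float)
        het = np.where(ok, sub == 1, False).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(n > 0, alt / (2 * n), np.nan)
            h_i[k] = np.where(n > 0, het / n, np.nan)
        n_i[k] = n
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n_i.mean(axis=0)
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2.0
    valid = (
        np.isfinite(a)
        & np.isfinite(b)
        & np.isfinite(c)
        & (n_bar > 1)
        & (n_c > 0)
        & (p_bar > 0)
        & (p_bar < 1)
        & np.all(n_i > 0, axis=0)
    )
    return a, b, c, valid


def _theta_multilocus(dosage, labels, pops) -> float:
    a, b, c, valid = _wc_components(dosage, labels, pops)
    denom = np.sum((a + b + c)[valid])
    if denom == 0 or not valid.any():
        return np.nan
    return float(np.sum(a[valid]) / denom)


def fst_wc(
    gd: GenotypeDataset,
    pop_a: str,
    pop_b: str,
    n_perm: int = 1000,
    seed: int | None = None,
):
    """Pairwise multilocus Weir–Cockerham θ with a permutation p-value.

    θ = Σa / Σ(a+b+c) over loci polymorphic in the pair; significance by
    permuting individuals between the two localities, p = (1 + #{θ* ≥ θ}) /
    (1 + n_perm).
    """
    mask = np.isin(gd.localities, [pop_a, pop_b])
    if np.sum(gd.localities == pop_a) < 2 or np.sum(gd.localities == pop_b) < 2:
        raise ValueError("both localities need at least 2 individuals")
    dos = gd.dosage[mask]
    labels = gd.localities[mask]
    theta = _theta_multilocus(dos, labels, [pop_a, pop_b])
    if n_perm <= 0:
        return theta, np.nan
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        t = _theta_multilocus(dos, perm, [pop_a, pop_b])
        if np.isnan(t):
            continue
        if t >= theta:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return theta, p


def fst_pairwise_matrix(gd: GenotypeDataset, n_perm: int = 1000, seed: int | None = None) -> PairwiseMatrix:
    """All pairwise θ and permutation p-values among localities."""
    pops = gd.pops
    n = len(pops)
    vals = np.zeros((n, n))
    ps = np.zeros((n, n))
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    seeds = ss.generate_state(n * n)
    for i in range(n):
        for j in range(i + 1, n):
            theta, p = fst_wc(gd, pops[i], pops[j], n_perm=n_perm, seed=int(seeds[i * n + j]))
            vals[i, j] = vals[j, i] = theta
            ps[i, j] = ps[j, i] = p
    return PairwiseMatrix(labels=pops, values=vals, pvalues=ps)


def fst_standardised(theta: float, hs: float, k: int = 2) -> float:
    """Hedrick-style standardisation: θ divided by its maximum given H_S.

    θ_max = (k−1)(1−H_S) / (k−1+H_S) for k subpopulations with mean within-
    population gene diversity H_S. Undefined (NaN) as H_S → 1.
    """
    if not (0.0 <= hs <= 1.0):
        raise ValueError("hs must lie in [0, 1]")
    if hs >= 1.0 - 1e-12:
        return np.nan
    theta_max = (k - 1) * (1.0 - hs) / (k - 1 + hs)
    return float(theta) / theta_max


def standardised_fst_transect(
    gd: GenotypeDataset,
    fst: PairwiseMatrix,
    positions: dict,
    n_perm: int = 0,
) -> pd.DataFrame:
    """Standardised pairwise θ ordered along a 1-D coastline transect.

    ``positions`` maps locality → coastline position (km, north→south or any
    monotone axis). Each pair contributes a point at the midpoint of the two
    localities, with plain θ and the Hedrick-standardised value computed from
    the pair's mean within-population expected heterozygosity.
    """
    div = diversity(gd)
    rows = []
    pops = fst.labels
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            a, b = pops[i], pops[j]
            hs = float(np.mean([div.loc[a, "He"], div.loc[b, "He"]]))
            theta = float(fst.values[i, j])
            rows.append(
                {
                    "pair": f"{a}-{b}",
                    "midpoint": 0.5 * (positions[a] + positions[b]),
                    "theta": theta,
                    "hs": hs,
                    "theta_std": fst_standardised(theta, hs, k=2),
                }
            )
    return pd.DataFrame(rows).sort_values("midpoint").reset_index(drop=True)


# ---------------------------------------------------------------- IBD Mantel

def geographic_distance_matrix(coords: pd.DataFrame, method: str = "euclidean") -> PairwiseMatrix:
    """Pairwise locality distances (km) from a locality/lon/lat table.

    ``euclidean`` projects to a local plane first (the convention used for
    isolation-by-distance here); ``great_circle`` uses haversine.
    """
    labels = coords.index.tolist() if coords.index.name else coords.iloc[:, 0].tolist()
    if "lon" in coords.columns:
        lon = coords["lon"].to_numpy(float)
        lat = coords["lat"].to_numpy(float)
    else:
        lon = coords.iloc[:, 1].to_numpy(float)
        lat = coords.iloc[:, 2].to_numpy(float)
    n = len(labels)
    d = np.zeros((n, n))
    if method == "euclidean":
        x, y = equirectangular_xy_km(lon, lat, lon.mean(), lat.mean())
        for i in range(n):
            for j in range(n):
                d[i, j] = np.hypot(x[i] - x[j], y[i] - y[j])
    elif method == "great_circle":
        for i in range(n):
            for j in range(n):
                d[i, j] = haversine_km(lon[i], lat[i], lon[j], lat[j])
    else:
        raise ValueError(f"unknown method {method!r}")
    return PairwiseMatrix(labels=labels, values=d)


def ibd_mantel(
    genetic: PairwiseMatrix,
    geographic: PairwiseMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
):
    """Simple Mantel test of isolation by distance.

    r is the Pearson correlation over upper-triangle entries; the one-sided
    p-value is the proportion of simultaneous row/column permutations with
    r* ≥ r, using the (1+count)/(1+n_perm) estimator.
    """
    if genetic.labels != geographic.labels:
        raise ValueError("matrices must share the same labels in the same order")
    n = len(genetic.labels)
    if n < 3:
        raise ValueError("Mantel test needs at least 3 localities")
    iu = np.triu_indices(n, k=1)
    x = genetic.values[iu]
    y = geographic.values[iu]
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = genetic.values[np.ix_(perm, perm)][iu]
        r = np.corrcoef(xp, y)[0, 1]
        if r >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return r_obs, p


# ---------------------------------------------------------------- outliers

def outlier_scan(gd: GenotypeDataset, n_perm: int = 999, seed: int | None = None) -> pd.DataFrame:
    """Permutation F_ST-outlier scan across all localities.

    Each locus's multi-population θ is compared against a null built by
    shuffling locality labels; two-sided p per locus (doubled one-sided
    tail) with Benjamini–Hochberg q-values. The permutation distribution of
    per-locus θ is heavily tied (permuted allele-count splits coincide, most
    often at low-MAF loci), so deterministic ≥/≤ counting is conservative;
    ties are instead split by a seeded uniform draw per locus, which makes
    the one-sided tail probabilities exactly uniform under the null.
    Monomorphic loci are excluded (NaN rows).
    """
    pops = gd.pops
    if len(pops) < 2:
        raise ValueError("outlier scan needs at least 2 localities")
    a, b, c, valid = _wc_components(gd.dosage, gd.localities, pops)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_obs = np.where(valid & ((a + b + c) != 0), a / (a + b + c), np.nan)
    rng = np.random.default_rng(seed)
    gt = np.zeros(gd.n_loci)
    lt = np.zeros(gd.n_loci)
    eq = np.zeros(gd.n_loci)
    nn = np.zeros(gd.n_loci)
    for _ in range(n_perm):
        perm = rng.permutation(gd.localities)
        ap, bp, cp, vp = _wc_components(gd.dosage, perm, pops)
        with np.errstate(invalid="ignore", divide="ignore"):
            tp = np.where(vp & ((ap + bp + cp) != 0), ap / (ap + bp + cp), np.nan)
        okp = np.isfinite(tp) & np.isfinite(theta_obs)
        tie = np.isclose(tp, theta_obs, rtol=1e-12, atol=1e-12)
        gt[okp] += (tp[okp] > theta_obs[okp]) & ~tie[okp]
        lt[okp] += (tp[okp] < theta_obs[okp]) & ~tie[okp]
        eq[okp] += tie[okp]
        nn[okp] += 1
    u = rng.random(gd.n_loci)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hi = (gt + u * (1 + eq)) / (1 + nn)
        p_lo = (lt + (1 - u) * (1 + eq)) / (1 + nn)
        p = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))
    p = np.where(np.isfinite(theta_obs) & (nn > 0), p, np.nan)
    q = np.full(gd.n_loci, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {"locus": gd.locus_ids, "theta_locus": theta_obs, "p": p, "q": q}
    ).set_index("locus")
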