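"""Genotypic distance matrices **F** from biallelic genotype tables.

Implements the four between-taxon genotypic distances used to build the
neutral expectation: Nei's standard distance, the Cavalli-Sforza & Edwards
chord distance, a Hudson-type pairwise F_ST, and Euclidean distance between
taxon centroids in Patterson's standardized PC space.  Genotypes are
alternate-allele counts (0/1/2, NaN = missing) with per-individual taxon
labels; IO is a plain CSV layout and a minimal GT-only VCF.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .distmat import DistanceMatrix


# ----------------------------------------------------------------------
# containers

@dataclass
class GenotypeTable:
    """Individuals x loci table of alternate-allele counts.

    ``genotypes`` is float so missing data can be NaN; defined entries must
    be 0, 1 or 2.
    """

    genotypes: np.ndarray            # (n_ind, n_loci)
    taxon: np.ndarray                # (n_ind,) labels
    locus_ids: tuple = ()
    individual_ids: tuple = ()

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.taxon = np.asarray(self.taxon, dtype=object)
        n, L = self.genotypes.shape
        if len(self.taxon) != n:
            raise ValueError("taxon labels do not match genotype rows")
        vals = self.genotypes[~np.isnan(self.genotypes)]
        if vals.size and not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
            raise ValueError("genotypes must be 0/1/2 or missing")
        if len(set(self.taxon)) < 2:
            raise ValueError("need at least two taxa")
        if L < 1:
            raise ValueError("need at least one locus")
        if not self.locus_ids:
            self.locus_ids = tuple(f"L{i+1}" for i in range(L))
        if not self.individual_ids:
            self.individual_ids = tuple(
                f"{t}_{i}" for i, t in enumerate(self.taxon))

    @property
    def taxa(self) -> tuple:
        seen = []
        for t in self.taxon:
            if t not in seen:
                seen.append(t)
        return tuple(seen)

    def rows(self, taxon: str) -> np.ndarray:
        return self.genotypes[self.taxon == taxon]

    # -- IO -------------------------------------------------------------
    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.genotypes, columns=list(self.locus_ids))
        df.insert(0, "taxon", list(self.taxon))
        df.insert(0, "individual", list(self.individual_ids))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GenotypeTable":
        df = pd.read_csv(path)
        loci = [c for c in df.columns if c not in ("individual", "taxon")]
        return cls(df[loci].to_numpy(float), df["taxon"].to_numpy(object),
                   tuple(loci), tuple(df["individual"].astype(str)))

    def to_vcf(self, path) -> None:
        """Minimal biallelic VCF, GT field only; taxon kept in sample names."""
        n, L = self.genotypes.shape
        gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=panmorph\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
            cols = "\t".join(self.individual_ids)
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
                     f"\t{cols}\n")
            for j in range(L):
                gts = []
                for i in range(n):
                    g = self.genotypes[i, j]
                    gts.append("./." if np.isnan(g) else gt_code[g])
                fh.write(f"1\t{j+1}\t{self.locus_ids[j]}\tA\tG\t.\t.\t.\tGT\t"
                         + "\t".join(gts) + "\n")

    @classmethod
    def from_vcf(cls, path, taxon_map: dict | None = None) -> "GenotypeTable":
        """Read a minimal biallelic VCF (GT field only).

        Taxon labels come from ``taxon_map`` (sample name -> taxon) or, by
        default, from the sample-name prefix before the last underscore.
        """
        samples, loci, rows = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("##") or not line:
                    continue
                parts = line.split("\t")
                if line.startswith("#CHROM"):
                    samples = parts[9:]
                    continue
                loci.append(parts[2])
                fmt = parts[8].split(":")
                gi = fmt.index("GT")
                row = []
                for entry in parts[9:]:
                    gt = entry.split(":")[gi].replace("|", "/")
                    if "." in gt:
                        row.append(np.nan)
                    else:
                        row.append(float(sum(int(a) for a in gt.split("/"))))
                rows.append(row)
        geno = np.asarray(rows, float).T
        if taxon_map is None:
            taxon = np.array([s.rsplit("_", 1)[0] for s in samples],
                             dtype=object)
        else:
            taxon = np.array([taxon_map[s] for s in samples], dtype=object)
        return cls(geno, taxon, tuple(loci), tuple(samples))


@dataclass
class AlleleFrequencies:
    """Per-taxon alternate-allele frequencies with allele sample sizes."""

    freqs: np.ndarray          # (n_taxa, n_loci), NaN where undefined
    sample_sizes: np.ndarray   # (n_taxa, n_loci) allele counts used
    taxa: tuple = ()
    locus_ids: tuple = ()

    def row(self, taxon: str) -> np.ndarray:
        return self.freqs[self.taxa.index(taxon)]


# ----------------------------------------------------------------------
# estimation

def allele_frequencies(table: GenotypeTable) -> AlleleFrequencies:
    """Alternate-allele frequency = allele count / (2 x non-missing)."""
    taxa = table.taxa
    K, L = len(taxa), table.genotypes.shape[1]
    freqs = np.full((K, L), np.nan)
    sizes = np.zeros((K, L))
    for k, t in enumerate(taxa):
        g = table.rows(t)
        nonmiss = np.sum(~np.isnan(g), axis=0)
        if np.any(nonmiss == 0):
            j = int(np.argmax(nonmiss == 0))
            raise ValueError(
                f"all genotypes missing for taxon {t!r} at locus "
                f"{table.locus_ids[j]!r}")
        sizes[k] = 2.0 * nonmiss
        freqs[k] = np.nansum(g, axis=0) / sizes[k]
    return AlleleFrequencies(freqs, sizes, taxa, table.locus_ids)


def _pair_freqs(freqs: AlleleFrequencies, a: str, b: str):
    pa, pb = freqs.row(a), freqs.row(b)
    ok = ~np.isnan(pa) & ~np.isnan(pb)
    if not ok.any():
        raise ValueError(f"no loci shared between {a!r} and {b!r}")
    return pa[ok], pb[ok]


def nei_standard_distance(freqs: AlleleFrequencies, a: str, b: str,
                          variant: str = "standard") -> float:
    """Nei's genetic distance between taxa ``a`` and ``b``.

    ``variant="standard"`` is Nei's standard distance
    D = -ln( J_ab / sqrt(J_a J_b) ) with the J homozygosity coefficients
    averaged over loci (biallelic: sums over both alleles).  Returns ``inf``
    when J_ab = 0 (alternately fixed profiles).  ``variant="da"`` gives
    Nei et al.'s D_A = 1 - mean_l sum_alleles sqrt(p_a p_b).
    """
    pa, pb = _pair_freqs(freqs, a, b)
    qa, qb = 1 - pa, 1 - pb
    if variant == "da":
        return float(1.0 - np.mean(np.sqrt(pa * pb) + np.sqrt(qa * qb)))
    if variant != "standard":
        raise ValueError(f"unknown variant {variant!r}")
    ja = np.mean(pa ** 2 + qa ** 2)
    jb = np.mean(pb ** 2 + qb ** 2)
    jab = np.mean(pa * pb + qa * qb)
    if jab <= 0:
        return float("inf")
    return float(-np.log(jab / np.sqrt(ja * jb)))


def chord_distance(freqs: AlleleFrequencies, a: str, b: str) -> float:
    """Cavalli-Sforza & Edwards chord distance, averaged over loci.

    Per-locus form (2/pi) * sqrt(2 * (1 - sum_alleles sqrt(p_a p_b))).
    """
    pa, pb = _pair_freqs(freqs, a, b)
    cos = np.sqrt(pa * pb) + np.sqrt((1 - pa) * (1 - pb))
    inner = np.clip(2.0 * (1.0 - cos), 0.0, None)
    return float(np.mean((2.0 / np.pi) * np.sqrt(inner)))


def hudson_fst_from_frequencies(p1, p2) -> float:
    """Frequency-level (infinite-sample) Hudson F_ST, ratio of averages."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    num = (p1 - p2) ** 2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    if not ok.any():
        raise ValueError("no polymorphic loci")
    return float(np.sum(num[ok]) / np.sum(den[ok]))


def fst_pairwise(table: GenotypeTable, a: str, b: str) -> float:
    """Hudson-type pairwise F_ST (Bhatia et al. ratio-of-averages).

    Per locus: num = (p1-p2)^2 - p1 q1/(n1-1) - p2 q2/(n2-1) with n the
    allele sample sizes; den = p1 q2 + p2 q1.  The numerator and denominator
    are each averaged over usable loci before the ratio.  Monomorphic-overall
    loci are skipped; the result is clipped to [0, 1].
    """
    freqs = allele_frequencies(table)
    ia, ib = freqs.taxa.index(a), freqs.taxa.index(b)
    p1, p2 = freqs.freqs[ia], freqs.freqs[ib]
    n1, n2 = freqs.sample_sizes[ia], freqs.sample_sizes[ib]
    ok = (~np.isnan(p1) & ~np.isnan(p2) & (n1 >= 2) & (n2 >= 2))
    # skip loci monomorphic across the pooled pair
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    ok &= (pooled > 0) & (pooled < 1)
    if not ok.any():
        raise ValueError(f"no usable loci for pair ({a!r}, {b!r})")
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(np.clip(np.sum(num) / np.sum(den), 0.0, 1.0))


def patterson_pc_distance(table: GenotypeTable, k: int | None = None
                          ) -> DistanceMatrix:
    """Euclidean distances between taxon centroids in Patterson's PC space.

    Columns are centered and divided by sqrt(p(1-p)) with p the column
    mean / 2; monomorphic columns are dropped; missing genotypes are imputed
    at the column mean before standardization.  PCA is over individuals;
    distances are between taxon centroids in the top-``k`` PCs
    (default: number of taxa - 1).
    """
    taxa = table.taxa
    if k is None:
        k = len(taxa) - 1
    G = table.genotypes.copy()
    colmean = np.nanmean(G, axis=0)
    miss = np.isnan(G)
    G[miss] = np.take(colmean, np.nonzero(miss)[1])
    p = colmean / 2.0
    poly = (p > 0) & (p < 1) & (np.std(G, axis=0) > 0)
    if not poly.any():
        raise ValueError("no polymorphic loci")
    M = (G[:, poly] - 2 * p[poly]) / np.sqrt(p[poly] * (1 - p[poly]))
    max_k = min(M.shape[0] - 1, M.shape[1])
    if k > max_k:
        raise ValueError(f"k={k} exceeds available components ({max_k})")
    scores = PCA(n_components=k, svd_solver="full").fit_transform(M)
    cents = np.stack([scores[table.taxon == t].mean(axis=0) for t in taxa])
    diff = cents[:, None, :] - cents[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=-1))
    return DistanceMatrix(taxa, D, kind="F_ppc", meta={"k": k})


def build_F_matrices(table: GenotypeTable, k: int | None = None) -> dict:
    """All four genotypic distance matrices, keyed by kind."""
    freqs = allele_frequencies(table)
    taxa = freqs.taxa
    K = len(taxa)
    out = {}
    for kind, fn in (
        ("F_nei", lambda a, b: nei_standard_distance(freqs, a, b)),
        ("F_chord", lambda a, b: chord_distance(freqs, a, b)),
        ("F_fst", lambda a, b: fst_pairwise(table, a, b)),
    ):
        D = np.zeros((K, K))
        for i, j in itertools.combinations(range(K), 2):
            D[i, j] = D[j, i] = fn(taxa[i], taxa[j])
        meta = {"variant": "standard"} if kind == "F_nei" else {}
        if kind == "F_chord":
            meta = {"variant": "(2/pi)*sqrt(2*(1-sum sqrt(pa*pb)))"}
        out[kind] = DistanceMatrix(taxa, D, kind=kind, meta=meta)
    out["F_ppc"] = patterson_pc_distance(table, k=k)
    return out


def allele_sharing_distance(g1: np.ndarray, g2: np.ndarray) -> float:
    """Individual-level distance: 1 - shared-allele proportion.

    For genotypes in {0,1,2} the per-locus shared-allele proportion is
    1 - |g1-g2|/2, so the distance is mean(|g1-g2|)/2 over non-missing loci.
    """
    d = np.abs(np.asarray(g1, float) - np.asarray(g2, float))
    ok = ~np.isnan(d)
    if not ok.any():
        raise ValueError("no shared non-missing loci")
    return float(np.mean(d[ok]) / 2.0)
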