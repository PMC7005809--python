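"""Single-QTL genome scans on haploid segregant populations.

The cross is a set of haploid meiotic segregants from two parents, so
every marker is biallelic with two genotype classes (A = first parent's
allele, B = second parent's) and the scan algebra is that of a
backcross.  Genotype probabilities at markers and at pseudomarkers on a
regular cM grid are computed with a two-state hidden Markov model using
the Haldane map function (no interference) and a symmetric genotyping
error rate.  Two phenotype models are provided:

* ``hk`` — Haley–Knott regression: the phenotype is regressed on
  P(allele A) at each position and LOD = (n/2)·log10(RSS0/RSS1).
* ``np`` — non-parametric: phenotypes are replaced by ranks (ties
  averaged) and a Kruskal–Wallis statistic generalised to genotype
  probabilities is used.  With weights p_i = P(allele A):

      n_A = Σ p_i,          n_B = n − n_A,
      r̄_A = Σ p_i r_i / n_A, r̄_B = Σ (1−p_i) r_i / n_B,
      H  = 12/(n(n+1)) · [n_A (r̄_A − r̄)² + n_B (r̄_B − r̄)²] / C_ties,
      LOD = H / (2 ln 10),

  which reduces to the exact two-group Kruskal–Wallis statistic at a
  fully informative marker.

Genome-wide significance comes from permutation of phenotype labels
(empirical (1−α) quantile of the per-permutation maximum LOD), support
intervals are 1-LOD drops converted to bp via the flanking markers, and
QTL detected for different traits are grouped into common loci when
their peaks are less than a cutoff (default 10 cM) apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "MarkerMap",
    "SegregantCross",
    "GenotypeProbabilities",
    "ScanResult",
    "QTLInterval",
    "FQTLGroup",
    "haldane",
    "inverse_haldane",
    "genotype_probabilities",
    "scan_hk",
    "scan_np",
    "permutation_threshold",
    "find_peaks",
    "lod_support_interval",
    "variance_explained",
    "lod_from_variance",
    "merge_models",
    "group_fqtls",
    "read_cross",
    "write_cross",
]

LN10 = np.log(10.0)


def haldane(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-0.02 * np.asarray(d_cm, dtype=float)))


def inverse_haldane(r: np.ndarray | float) -> np.ndarray | float:
    """Genetic distance (cM) for a recombination fraction."""
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r, dtype=float))


# -- data containers -------------------------------------------------

@dataclass
class MarkerMap:
    """Marker table with genetic (cM) and physical (bp) coordinates."""

    table: pd.DataFrame  # columns: marker, chrom, cm, bp

    def __post_init__(self) -> None:
        req = {"marker", "chrom", "cm", "bp"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"marker map missing columns {req - set(self.table.columns)}")
        if self.table["marker"].duplicated().any():
            raise ValueError("duplicate marker ids")
        for chrom, sub in self.table.groupby("chrom", sort=False):
            if not (sub["cm"].is_monotonic_increasing
                    and sub["bp"].is_monotonic_increasing):
                raise ValueError(f"chromosome {chrom}: positions not sorted")

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_table(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]


@dataclass
class SegregantCross:
    """Haploid biallelic cross: map + genotypes + phenotypes.

    Genotypes are coded 1.0 (allele A), 0.0 (allele B), NaN (missing);
    rows are segregants, columns markers in map order.
    """

    markers: MarkerMap
    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.genotypes.columns) != list(self.markers.table["marker"]):
            raise ValueError("genotype columns do not match the marker map")
        if not self.genotypes.index.equals(self.phenotypes.index):
            raise ValueError("genotype and phenotype individuals differ")
        vals = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            raise ValueError("genotypes must be coded 0/1/NaN (haploid biallelic)")

    @property
    def individuals(self) -> list[str]:
        return list(self.genotypes.index)


@dataclass
class GenotypeProbabilities:
    """P(allele A) at markers and pseudomarkers for every individual."""

    positions: pd.DataFrame         # columns: chrom, cm, is_pseudo, marker
    prob_a: np.ndarray              # individuals × positions
    individuals: list[str]
    step_cm: float

    def chrom_slice(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.positions["chrom"] == chrom).to_numpy())


@dataclass
class ScanResult:
    """LOD curve for one trait under one phenotype model."""

    trait: str
    model: str                      # 'hk' or 'np'
    positions: pd.DataFrame         # chrom, cm, is_pseudo, marker
    lod: np.ndarray
    threshold: float | None = None
    n_used: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("hk", "np"):
            raise ValueError(f"unknown scan model {self.model!r}")
        if len(self.lod) != len(self.positions):
            raise ValueError("lod length does not match positions")

    def to_frame(self) -> pd.DataFrame:
        out = self.positions.copy()
        out["lod"] = self.lod
        return out


@dataclass
class QTLInterval:
    """1-LOD support interval around a scan peak."""

    trait: str
    chromosome: object
    start_bp: int
    end_bp: int
    peak_cm: float
    peak_lod: float
    model: str

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("interval start exceeds end")

    @property
    def name(self) -> str:
        return f"chr{self.chromosome}@{self.peak_cm:.1f}"


@dataclass
class FQTLGroup:
    """QTL of several traits whose peaks co-locate on one chromosome."""

    name: str
    chromosome: object
    members: list[QTLInterval]
    start_bp: int
    end_bp: int
    max_lod: float

    @property
    def traits(self) -> list[str]:
        return sorted({m.trait for m in self.members})


# -- genotype probabilities ------------------------------------------

def _emission(geno_col: np.ndarray, error_rate: float) -> np.ndarray:
    """(individuals × 2) emission likelihoods for one observed marker."""
    n = len(geno_col)
    e = np.ones((n, 2))
    obs = ~np.isnan(geno_col)
    ga = obs & (geno_col == 1.0)
    gb = obs & (geno_col == 0.0)
    # state order: [B, A]
    e[ga, 1] = 1.0 - error_rate
    e[ga, 0] = error_rate
    e[gb, 0] = 1.0 - error_rate
    e[gb, 1] = error_rate
    return e


def _position_grid(chrom_markers: pd.DataFrame, step_cm: float) -> pd.DataFrame:
    """Marker positions plus pseudomarkers every ``step_cm`` from the start."""
    cms = chrom_markers["cm"].to_numpy(dtype=float)
    names = chrom_markers["marker"].to_numpy()
    grid = np.arange(cms[0], cms[-1] + 1e-9, step_cm)
    rows = [(cm, False, mk) for cm, mk in zip(cms, names)]
    for g in grid:
        if np.min(np.abs(cms - g)) > 1e-6:
            rows.append((g, True, ""))
    rows.sort(key=lambda r: (r[0], r[1]))
    return pd.DataFrame(rows, columns=["cm", "is_pseudo", "marker"])


def genotype_probabilities(
    cross: SegregantCross,
    step_cm: float = 2.5,
    error_rate: float = 1e-4,
) -> GenotypeProbabilities:
    """Forward–backward smoothing of P(allele A) along each chromosome.

    At an observed marker with ``error_rate`` 0 the posterior is exactly
    0 or 1; a fully missing individual gets 0.5 everywhere.
    """
    if step_cm <= 0:
        raise ValueError("pseudomarker step must be positive")
    if not (0.0 <= error_rate < 0.5):
        raise ValueError("error rate must be in [0, 0.5)")
    geno = cross.genotypes.to_numpy(dtype=float)
    n_ind = geno.shape[0]
    all_pos = []
    probs = []
    marker_col = {mk: j for j, mk in enumerate(cross.genotypes.columns)}
    for chrom in cross.markers.chromosomes:
        sub = cross.markers.chrom_table(chrom)
        grid = _position_grid(sub, step_cm)
        n_pos = len(grid)
        emis = np.ones((n_pos, n_ind, 2))
        for t, row in enumerate(grid.itertuples(index=False)):
            if not row.is_pseudo:
                emis[t] = _emission(geno[:, marker_col[row.marker]], error_rate)
        d = np.diff(grid["cm"].to_numpy(dtype=float))
        r = np.asarray(haldane(d))

        fwd = np.empty((n_pos, n_ind, 2))
        a = 0.5 * emis[0]
        fwd[0] = a / a.sum(axis=1, keepdims=True)
        for t in range(1, n_pos):
            stay, flip = 1.0 - r[t - 1], r[t - 1]
            pred = np.empty_like(a)
            pred[:, 0] = fwd[t - 1][:, 0] * stay + fwd[t - 1][:, 1] * flip
            pred[:, 1] = fwd[t - 1][:, 1] * stay + fwd[t - 1][:, 0] * flip
            a = pred * emis[t]
            fwd[t] = a / a.sum(axis=1, keepdims=True)

        bwd = np.empty((n_pos, n_ind, 2))
        bwd[-1] = 1.0
        for t in range(n_pos - 2, -1, -1):
            stay, flip = 1.0 - r[t], r[t]
            nxt = bwd[t + 1] * emis[t + 1]
            bwd[t][:, 0] = nxt[:, 0] * stay + nxt[:, 1] * flip
            bwd[t][:, 1] = nxt[:, 1] * stay + nxt[:, 0] * flip
            bwd[t] /= bwd[t].sum(axis=1, keepdims=True)

        post = fwd * bwd
        post /= post.sum(axis=2, keepdims=True)
        probs.append(post[:, :, 1].T)  # individuals × positions, P(A)
        grid.insert(0, "chrom", chrom)
        all_pos.append(grid)

    positions = pd.concat(all_pos, ignore_index=True)
    prob_a = np.hstack(probs)
    return GenotypeProbabilities(positions, prob_a, cross.individuals, step_cm)


# -- scans -----------------------------------------------------------

def _prepare_phenotype(probs: GenotypeProbabilities,
                       phenotype: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    y = phenotype.reindex(probs.individuals).to_numpy(dtype=float)
    keep = ~np.isnan(y)
    if keep.sum() < 3:
        raise ValueError("need at least 3 non-missing phenotype values")
    return y[keep], probs.prob_a[keep]


def _hk_lods(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """LOD for each position (rows of Xᵀ) × each phenotype column of Y."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0, keepdims=True)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    sxx = np.einsum("ij,ij->j", Xc, Xc)            # per position
    syy = np.einsum("ik,ik->k", Yc, Yc)            # per phenotype
    sxy = Xc.T @ Yc                                # positions × phenotypes
    with np.errstate(divide="ignore", invalid="ignore"):
        rss1 = syy[None, :] - np.where(sxx[:, None] > 0,
                                       sxy ** 2 / np.where(sxx[:, None] > 0,
                                                           sxx[:, None], 1.0),
                                       0.0)
    rss1 = np.clip(rss1, 1e-300, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = 0.5 * n * np.log10(syy[None, :] / rss1)
    lod[:, syy == 0] = 0.0
    return np.clip(lod, 0.0, None)


def scan_hk(probs: GenotypeProbabilities, phenotype: pd.Series,
            trait: str = "") -> ScanResult:
    """Haley–Knott regression scan: y ~ P(allele A) at every position."""
    y, X = _prepare_phenotype(probs, phenotype)
    if np.var(y) == 0:
        warnings.warn(f"trait {trait or phenotype.name}: zero phenotypic variance",
                      stacklevel=2)
        lod = np.zeros(X.shape[1])
    else:
        lod = _hk_lods(X, y[:, None])[:, 0]
    return ScanResult(trait or str(phenotype.name), "hk",
                      probs.positions.copy(), lod, n_used=len(y))


def _np_lods(X: np.ndarray, R: np.ndarray, tie_corr: np.ndarray) -> np.ndarray:
    """Rank-based LOD per position × rank-vector column."""
    n = X.shape[0]
    rbar = (n + 1) / 2.0
    na = X.sum(axis=0)                              # per position
    nb = n - na
    sa = X.T @ R                                    # positions × perms
    sb = R.sum(axis=0)[None, :] - sa
    with np.errstate(divide="ignore", invalid="ignore"):
        da = np.where(na[:, None] > 1e-12, sa / na[:, None], rbar) - rbar
        db = np.where(nb[:, None] > 1e-12, sb / nb[:, None], rbar) - rbar
    h = 12.0 / (n * (n + 1)) * (na[:, None] * da ** 2 + nb[:, None] * db ** 2)
    h = h / tie_corr[None, :]
    return h / (2.0 * LN10)


def _tie_correction(y: np.ndarray) -> float:
    n = len(y)
    _, counts = np.unique(y, return_counts=True)
    c = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return c if c > 0 else 1.0


def scan_np(probs: GenotypeProbabilities, phenotype: pd.Series,
            trait: str = "") -> ScanResult:
    """Non-parametric (rank-based) scan; see module docstring for the form."""
    y, X = _prepare_phenotype(probs, phenotype)
    if np.var(y) == 0:
        warnings.warn(f"trait {trait or phenotype.name}: zero phenotypic variance",
                      stacklevel=2)
        lod = np.zeros(X.shape[1])
    else:
        r = rankdata(y)
        lod = _np_lods(X, r[:, None], np.array([_tie_correction(y)]))[:, 0]
    return ScanResult(trait or str(phenotype.name), "np",
                      probs.positions.copy(), np.clip(lod, 0.0, None),
                      n_used=len(y))


def permutation_threshold(
    probs: GenotypeProbabilities,
    phenotype: pd.Series,
    model: str = "hk",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> float:
    """Genome-wide LOD threshold from phenotype-label permutations.

    The per-permutation maximum LOD over all positions is recorded and
    the empirical (1−α) quantile returned (α = 0 gives the maximum).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    y, X = _prepare_phenotype(probs, phenotype)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(y)
    perm = np.empty((n, n_perm))
    if model == "np":
        base = rankdata(y)
        tc = np.full(n_perm, _tie_correction(y))
    else:
        base = y
    for k in range(n_perm):
        perm[:, k] = rng.permutation(base)
    if model == "hk":
        lods = _hk_lods(X, perm)
    elif model == "np":
        lods = _np_lods(X, perm, tc)
    else:
        raise ValueError(f"unknown scan model {model!r}")
    max_lod = lods.max(axis=0)
    return float(np.quantile(max_lod, 1.0 - alpha, method="higher"))


# -- peaks, intervals, grouping --------------------------------------

def find_peaks(scan: ScanResult, threshold: float) -> list[tuple]:
    """Highest position above threshold per chromosome (leftmost on ties)."""
    peaks = []
    pos = scan.positions
    for chrom in dict.fromkeys(pos["chrom"]):
        idx = np.flatnonzero((pos["chrom"] == chrom).to_numpy())
        lods = scan.lod[idx]
        if lods.max() < threshold or lods.max() <= 0:
            continue
        best = idx[int(np.argmax(lods))]  # argmax returns first (leftmost)
        peaks.append((chrom, float(pos["cm"].iloc[best]), float(scan.lod[best])))
    return peaks


def lod_support_interval(
    scan: ScanResult,
    peak: tuple,
    marker_map: MarkerMap,
    drop: float = 1.0,
    threshold: float | None = None,
) -> QTLInterval | None:
    """Support interval: positions contiguous with the peak whose LOD
    stays within ``drop`` of the peak LOD (boundary included), with ends
    converted to bp via the nearest flanking markers."""
    chrom, peak_cm, peak_lod = peak
    if threshold is not None and peak_lod < threshold:
        return None
    pos = scan.positions
    idx = np.flatnonzero((pos["chrom"] == chrom).to_numpy())
    cms = pos["cm"].to_numpy(dtype=float)[idx]
    lods = scan.lod[idx]
    p = int(np.argmin(np.abs(cms - peak_cm)))
    lo = p
    while lo > 0 and lods[lo - 1] >= peak_lod - drop:
        lo -= 1
    hi = p
    while hi < len(idx) - 1 and lods[hi + 1] >= peak_lod - drop:
        hi += 1
    left_cm, right_cm = cms[lo], cms[hi]
    sub = marker_map.chrom_table(chrom)
    mcm = sub["cm"].to_numpy(dtype=float)
    mbp = sub["bp"].to_numpy()
    left_candidates = np.flatnonzero(mcm <= left_cm + 1e-9)
    right_candidates = np.flatnonzero(mcm >= right_cm - 1e-9)
    start_bp = int(mbp[left_candidates[-1]] if len(left_candidates) else mbp[0])
    end_bp = int(mbp[right_candidates[0]] if len(right_candidates) else mbp[-1])
    return QTLInterval(scan.trait, chrom, start_bp, end_bp,
                       float(peak_cm), float(peak_lod), scan.model)


def variance_explained(lod: float, n: int) -> float:
    """Fraction of trait variance explained by a locus with a given LOD."""
    if lod < 0:
        raise ValueError("LOD must be non-negative")
    if n < 2:
        raise ValueError("need n >= 2")
    return 1.0 - 10.0 ** (-2.0 * lod / n)


def lod_from_variance(fraction: float, n: int) -> float:
    """Inverse of :func:`variance_explained`."""
    return -0.5 * n * np.log10(1.0 - fraction)


def merge_models(
    hk: ScanResult,
    np_scan: ScanResult,
    marker_map: MarkerMap,
    drop: float = 1.0,
    grouping_cm: float = 10.0,
) -> list[QTLInterval]:
    """Per-locus selection between the two phenotype models.

    Loci detected by both scans with peaks within ``grouping_cm`` keep
    the higher-LOD version; loci detected by only one model pass
    through.  Both scans must carry their permutation thresholds.
    """
    if hk.trait != np_scan.trait:
        raise ValueError("scans are for different traits")
    if not hk.positions[["chrom", "cm"]].equals(np_scan.positions[["chrom", "cm"]]):
        raise ValueError("scans use different maps")
    intervals: list[QTLInterval] = []
    for scan in (hk, np_scan):
        thr = scan.threshold if scan.threshold is not None else 0.0
        for peak in find_peaks(scan, thr):
            iv = lod_support_interval(scan, peak, marker_map, drop=drop)
            if iv is not None:
                intervals.append(iv)
    # cluster per chromosome, keep the best member of each cluster
    selected: list[QTLInterval] = []
    for chrom in dict.fromkeys(iv.chromosome for iv in intervals):
        members = sorted((iv for iv in intervals if iv.chromosome == chrom),
                         key=lambda iv: iv.peak_cm)
        cluster: list[QTLInterval] = []
        for iv in members:
            if cluster and iv.peak_cm - cluster[-1].peak_cm >= grouping_cm:
                selected.append(max(cluster, key=lambda q: q.peak_lod))
                cluster = []
            cluster.append(iv)
        if cluster:
            selected.append(max(cluster, key=lambda q: q.peak_lod))
    return selected


def group_fqtls(intervals: list[QTLInterval],
                max_distance_cm: float = 10.0) -> list[FQTLGroup]:
    """Single-linkage clustering of QTL peaks into common loci.

    Intervals (possibly for different traits) on the same chromosome
    whose peaks chain at < ``max_distance_cm`` form one group; group
    borders are the union of member borders and the group LOD is the
    maximum member LOD.  Names follow the chrN@peak-cM convention using
    the peak of the highest-LOD member.
    """
    groups: list[FQTLGroup] = []
    for chrom in dict.fromkeys(iv.chromosome for iv in intervals):
        members = sorted((iv for iv in intervals if iv.chromosome == chrom),
                         key=lambda iv: iv.peak_cm)
        cluster: list[QTLInterval] = []

        def _flush(cluster: list[QTLInterval]) -> None:
            best = max(cluster, key=lambda q: q.peak_lod)
            groups.append(FQTLGroup(
                name=f"chr{chrom}@{best.peak_cm:.1f}",
                chromosome=chrom,
                members=list(cluster),
                start_bp=min(q.start_bp for q in cluster),
                end_bp=max(q.end_bp for q in cluster),
                max_lod=best.peak_lod,
            ))

        for iv in members:
            if cluster and iv.peak_cm - cluster[-1].peak_cm >= max_distance_cm:
                _flush(cluster)
                cluster = []
            cluster.append(iv)
        if cluster:
            _flush(cluster)
    return groups


# -- cross file I/O --------------------------------------------------

def write_cross(cross: SegregantCross, path: str | Path,
                bp_sidecar: str | Path | None = None) -> None:
    """Rotated cross CSV (traits as first rows, then marker rows) plus a
    sidecar CSV with physical positions."""
    path = Path(path)
    inds = cross.individuals
    rows = []
    for trait in cross.phenotypes.columns:
        rows.append([trait, "", ""] + list(cross.phenotypes[trait].values))
    code = {1.0: "A", 0.0: "B"}
    for mk, chrom, cm in zip(cross.markers.table["marker"],
                             cross.markers.table["chrom"],
                             cross.markers.table["cm"]):
        calls = [code.get(v, "-") if not pd.isna(v) else "-"
                 for v in cross.genotypes[mk]]
        rows.append([mk, chrom, cm] + calls)
    pd.DataFrame(rows, columns=["id", "chrom", "cm"] + inds).to_csv(path, index=False)
    sidecar = Path(bp_sidecar) if bp_sidecar else path.with_suffix(".bp.csv")
    cross.markers.table[["marker", "bp"]].to_csv(sidecar, index=False)


def read_cross(path: str | Path,
               bp_sidecar: str | Path | None = None) -> SegregantCross:
    """Inverse of :func:`write_cross`."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"chrom": str})
    inds = list(df.columns[3:])
    is_marker = df["chrom"].notna() & (df["chrom"].astype(str) != "")
    pheno_rows = df[~is_marker]
    marker_rows = df[is_marker]
    phenotypes = pd.DataFrame(
        {r.id: pd.to_numeric(pd.Series(list(r[3:]), index=inds), errors="coerce")
         for r in pheno_rows.itertuples(index=False)}, index=inds)
    sidecar = Path(bp_sidecar) if bp_sidecar else path.with_suffix(".bp.csv")
    bp = pd.read_csv(sidecar).set_index("marker")["bp"]
    mk_table = pd.DataFrame({
        "marker": marker_rows["id"].values,
        "chrom": marker_rows["chrom"].values,
        "cm": pd.to_numeric(marker_rows["cm"]).values,
        "bp": bp.reindex(marker_rows["id"]).values,
    })
    code = {"A": 1.0, "B": 0.0}
    geno = pd.DataFrame(
        {r.id: [code.get(str(v).strip(), np.nan) for v in r[3:]]
         for r in marker_rows.itertuples(index=False)}, index=inds)
    geno.columns.name = "marker"
    return SegregantCross(MarkerMap(mk_table), geno, phenotypes)
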