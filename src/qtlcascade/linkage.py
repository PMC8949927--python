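"""Single-QTL genome scan for an N2 backcross.

Interval mapping by an EM normal-mixture fit at pseudomarker grid
positions, permutation-based genome-wide significance thresholds, and
peak-marker effect summaries.

The backcross has two genotype classes: homozygous for the recurrent
strain (``NN``) and heterozygous (``NB``).  At a grid position the
phenotype is modelled as a two-component normal mixture with mixing
weights given by the conditional genotype probabilities from flanking
markers (no crossover interference; Haldane map function).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: integer genotype codes used in :class:`GenotypeMatrix`
NN = 0
NB = 1
MISSING = -1

GENOTYPE_LABELS = {NN: "NN", NB: "NB", MISSING: "NA"}
GENOTYPE_CODES = {"NN": NN, "NB": NB, "NA": MISSING, "": MISSING}

_LN10 = np.log(10.0)
_SIGMA2_FLOOR = 1e-12


def haldane(d):
    """Map distance (Morgan) -> recombination fraction, r = (1 - e^(-2d)) / 2.

    Accepts scalars or arrays; distances must be non-negative.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    return r if r.ndim else float(r)


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map for one chromosome (bp and cM coordinates)."""

    chromosome: str
    markers: tuple
    position_bp: np.ndarray
    position_cm: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(
            self, "position_bp", np.asarray(self.position_bp, dtype=np.int64)
        )
        object.__setattr__(
            self, "position_cm", np.asarray(self.position_cm, dtype=float)
        )
        n = len(self.markers)
        if not (len(self.position_bp) == len(self.position_cm) == n):
            raise ValueError("markers, bp and cM arrays must have equal length")
        if n == 0:
            raise ValueError("empty genetic map")
        if np.any(np.diff(self.position_bp) <= 0):
            raise ValueError("bp positions must be strictly increasing")
        # ties allowed in cM (fully linked markers), never decreases
        if np.any(np.diff(self.position_cm) < 0):
            raise ValueError("cM positions must be non-decreasing")
        if self.position_cm[0] < 0:
            raise ValueError("cM positions must be non-negative")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def span_bp(self):
        return int(self.position_bp[0]), int(self.position_bp[-1])

    def cm_at(self, bp):
        """Interpolate genetic position (cM) at physical position(s)."""
        return np.interp(np.asarray(bp, dtype=float),
                         self.position_bp.astype(float), self.position_cm)

    def index_of(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in map") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": list(self.markers),
                "chrom": self.chromosome,
                "position_bp": self.position_bp,
                "position_cm": self.position_cm,
            }
        )


@dataclass
class GenotypeMatrix:
    """N2 individuals x markers, integer codes {NN=0, NB=1, missing=-1}."""

    individuals: list
    genmap: GeneticMap
    codes: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        n, m = self.codes.shape
        if len(self.individuals) != n:
            raise ValueError("individual ids do not match genotype rows")
        if m != self.genmap.n_markers:
            raise ValueError("genotype columns do not match map markers")
        if not np.isin(self.codes, [NN, NB, MISSING]).all():
            raise ValueError("genotype codes must be in {0, 1, -1}")
        if np.any((self.codes == MISSING).all(axis=1)):
            raise ValueError("individual with no non-missing genotype")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    def column(self, marker: str) -> np.ndarray:
        return self.codes[:, self.genmap.index_of(marker)]

    def to_frame(self) -> pd.DataFrame:
        labels = np.vectorize(GENOTYPE_LABELS.get)(self.codes)
        return pd.DataFrame(labels, index=pd.Index(self.individuals, name="individual"),
                            columns=list(self.genmap.markers))


@dataclass
class PhenotypeTable:
    """Named quantitative traits per individual; NaN marks missing."""

    data: pd.DataFrame

    def __post_init__(self):
        self.data = pd.DataFrame(self.data)
        self.data.index.name = "individual"

    @property
    def traits(self) -> list:
        return list(self.data.columns)

    def trait(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"unknown trait {name!r}")
        return self.data[name]

    def aligned_to(self, geno: GenotypeMatrix) -> "PhenotypeTable":
        missing = set(geno.individuals) - set(self.data.index)
        if missing:
            raise ValueError(f"phenotypes missing for individuals: {sorted(missing)[:5]}")
        return PhenotypeTable(self.data.loc[list(geno.individuals)])


@dataclass
class LodCurve:
    """LOD profile over a pseudomarker grid with per-position mixture fits."""

    chromosome: str
    position_bp: np.ndarray
    position_cm: np.ndarray
    lod: np.ndarray
    mu_nn: np.ndarray
    mu_nb: np.ndarray
    sigma: np.ndarray
    trait: str = ""

    def peak(self):
        """(position_bp, lod) at the maximum; leftmost position on ties."""
        i = int(np.argmax(self.lod))
        return int(self.position_bp[i]), float(self.lod[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_bp": self.position_bp.astype(np.int64),
                "position_cm": self.position_cm,
                "lod": self.lod,
                "mu_nn": self.mu_nn,
                "mu_nb": self.mu_nb,
                "sigma": self.sigma,
            }
        )


@dataclass
class PermutationNull:
    """Genome-wide max-LOD null distribution and its (1 - alpha) threshold."""

    max_lod: np.ndarray
    alpha: float

    def __post_init__(self):
        self.max_lod = np.asarray(self.max_lod, dtype=float)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.max_lod.size == 0:
            raise ValueError("no permutation maxima")

    @property
    def n_perm(self) -> int:
        return int(self.max_lod.size)

    @property
    def threshold(self) -> float:
        # type-7 (linear interpolation) quantile, numpy's default
        return float(np.quantile(self.max_lod, 1.0 - self.alpha, method="linear"))


@dataclass
class PeakEffectSummary:
    """Per-genotype-class trait summaries and test results at a peak marker."""

    marker: str
    position_bp: int
    trait: str
    class_stats: pd.DataFrame  # index: class label; columns n, mean, sem
    test: str                  # "welch-t" or "anova-bonferroni"
    p_values: dict             # comparison label -> (adjusted) p-value


# ---------------------------------------------------------------------------
# conditional genotype probabilities


def _flank_probs(code, d_morgan):
    """P(NN) at the scan position given one flanking genotype.

    ``code`` and ``d_morgan`` are arrays; missing codes get the 0.5 prior.
    """
    r = haldane(d_morgan)
    p_nn = np.where(code == NN, 1.0 - r, r)
    return np.where(code == MISSING, 0.5, p_nn)


def genotype_probabilities(geno: GenotypeMatrix, position_bp) -> np.ndarray:
    """Per-individual P(NN), P(NB) at one position (shape (n, 2)).

    Conditions on the nearest informative marker on each side assuming no
    interference, so the chain factorises across the two flanks.  With no
    informative flank on either side the prior (0.5, 0.5) is returned.
    """
    gmap = geno.genmap
    lo, hi = gmap.span_bp
    if not lo <= position_bp <= hi:
        raise ValueError(f"position {position_bp} outside map span [{lo}, {hi}]")
    return _probability_grid(geno, np.asarray([position_bp]))[:, 0, :]


def _probability_grid(geno: GenotypeMatrix, positions_bp) -> np.ndarray:
    """P(NN), P(NB) for each individual at each position (n, G, 2)."""
    gmap = geno.genmap
    codes = geno.codes  # (n, m)
    n, m = codes.shape
    positions_bp = np.asarray(positions_bp, dtype=np.int64)
    pos_cm = gmap.cm_at(positions_bp)  # (G,)
    marker_cm = gmap.position_cm
    G = len(positions_bp)

    observed = codes != MISSING  # (n, m)
    # nearest informative marker index at or left of each grid position
    # and at or right of it, per individual
    p_nn = np.empty((n, G))
    left_idx = np.searchsorted(marker_cm, pos_cm, side="right") - 1  # (G,)
    right_idx = np.searchsorted(marker_cm, pos_cm, side="left")      # (G,)

    # per individual, cumulative nearest-informative bookkeeping
    idx = np.arange(m)
    # last informative marker index <= j (per individual), -1 if none
    last_inf = np.where(observed, idx[None, :], -1)
    last_inf = np.maximum.accumulate(last_inf, axis=1)
    # first informative marker index >= j, m if none
    next_inf = np.where(observed, idx[None, :], m)
    next_inf = np.minimum.accumulate(next_inf[:, ::-1], axis=1)[:, ::-1]

    for g in range(G):
        li, ri = left_idx[g], right_idx[g]
        # exact hit on an informative marker: deterministic
        lmark = last_inf[:, li] if li >= 0 else np.full(n, -1)
        rmark = next_inf[:, ri] if ri < m else np.full(n, m)
        has_l = lmark >= 0
        has_r = rmark < m
        d_l = np.where(has_l, (pos_cm[g] - marker_cm[np.clip(lmark, 0, m - 1)]) / 100.0, 0.0)
        d_r = np.where(has_r, (marker_cm[np.clip(rmark, 0, m - 1)] - pos_cm[g]) / 100.0, 0.0)
        code_l = np.where(has_l, codes[np.arange(n), np.clip(lmark, 0, m - 1)], MISSING)
        code_r = np.where(has_r, codes[np.arange(n), np.clip(rmark, 0, m - 1)], MISSING)
        a = _flank_probs(code_l, np.maximum(d_l, 0.0))
        b = _flank_probs(code_r, np.maximum(d_r, 0.0))
        num = a * b
        den = num + (1.0 - a) * (1.0 - b)
        p_nn[:, g] = num / den
    n_uninformative = int(((last_inf < 0).all(axis=1)).sum())
    if n_uninformative:
        log.warning("%d individuals with no informative markers: uniform prior used",
                    n_uninformative)
    return np.stack([p_nn, 1.0 - p_nn], axis=2)


# ---------------------------------------------------------------------------
# EM mixture scan


def _null_loglik(y: np.ndarray) -> float:
    n = y.size
    s2 = float(np.var(y))
    if s2 <= _SIGMA2_FLOOR:
        raise ValueError("phenotype has zero variance")
    return -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)


def _em_core(P, y, tol=1e-8, max_iter=1000, check_monotone=True):
    """Vectorised EM over grid positions.

    P : (G, n, 2) prior class probabilities; y : (n,) phenotypes.
    Returns (loglik, mu, sigma2) with shapes (G,), (G, 2), (G,).
    """
    G, n, _ = P.shape
    ybar, s2_0 = float(np.mean(y)), float(np.var(y))
    mu = np.full((G, 2), ybar)
    sigma2 = np.full(G, s2_0)
    loglik = np.full(G, -np.inf)
    active = np.ones(G, dtype=bool)
    y2 = y[None, :, None]  # broadcast helper
    converged_at = np.full(G, max_iter)

    for it in range(max_iter):
        if not active.any():
            break
        Pa = P[active]
        mua = mu[active]
        s2a = sigma2[active][:, None, None]
        resid = y2 - mua[:, None, :]  # (Ga, n, 2)
        dens = np.exp(-0.5 * resid**2 / s2a) / np.sqrt(2.0 * np.pi * s2a)
        joint = Pa * dens
        tot = joint.sum(axis=2)  # (Ga, n)
        ll_new = np.log(np.maximum(tot, 1e-300)).sum(axis=1)
        if check_monotone and it > 0:
            drop = loglik[active] - ll_new
            if np.any(drop > 1e-6):
                raise AssertionError("EM log-likelihood decreased")
        w = joint / np.maximum(tot, 1e-300)[:, :, None]
        sw = w.sum(axis=1)  # (Ga, 2)
        mu_new = np.where(
            sw > 1e-12, (w * y2).sum(axis=1) / np.maximum(sw, 1e-12), mua
        )
        resid_new = y2 - mu_new[:, None, :]
        s2_new = np.maximum((w * resid_new**2).sum(axis=(1, 2)) / n, _SIGMA2_FLOOR)

        delta = np.abs(ll_new - loglik[active])
        mu[active] = mu_new
        sigma2[active] = s2_new
        loglik[active] = ll_new
        done = delta < tol
        ga = np.flatnonzero(active)
        converged_at[ga[done]] = it
        active[ga[done]] = False
    else:
        if active.any():
            warnings.warn(
                f"EM did not converge at {int(active.sum())} positions after "
                f"{max_iter} iterations; returning current values",
                RuntimeWarning,
                stacklevel=2,
            )
    # one final E-step evaluation so loglik matches returned parameters
    resid = y2 - mu[:, None, :]
    s2 = sigma2[:, None, None]
    dens = np.exp(-0.5 * resid**2 / s2) / np.sqrt(2.0 * np.pi * s2)
    loglik = np.log(np.maximum((P * dens).sum(axis=2), 1e-300)).sum(axis=1)
    return loglik, mu, sigma2


def _scan_grid(gmap: GeneticMap, step_bp: int) -> np.ndarray:
    lo, hi = gmap.span_bp
    grid = np.arange(lo, hi + 1, step_bp, dtype=np.int64)
    if grid[-1] != hi:
        grid = np.append(grid, hi)
    return grid


def em_scan(
    geno: GenotypeMatrix,
    pheno,
    step_bp: int = 500_000,
    trait: str = "",
    tol: float = 1e-8,
    max_iter: int = 1000,
    _prob_grid=None,
    _positions=None,
) -> LodCurve:
    """EM interval-mapping scan of one trait over a pseudomarker grid.

    ``pheno`` is a phenotype vector aligned to ``geno`` rows (NaN dropped
    together with the corresponding genotype rows).  LOD at a position is
    log10 L1 - log10 L0 where L1 is the converged two-component mixture
    likelihood and L0 the single-normal MLE likelihood.
    """
    y = np.asarray(pheno, dtype=float)
    if y.shape[0] != geno.n_individuals:
        raise ValueError("phenotype length does not match genotype rows")
    keep = ~np.isnan(y)
    if keep.sum() < 2:
        raise ValueError("need at least 2 individuals with non-missing phenotype")
    y = y[keep]

    if _positions is None:
        positions = _scan_grid(geno.genmap, step_bp)
    else:
        positions = np.asarray(_positions, dtype=np.int64)
    if _prob_grid is None:
        sub = GenotypeMatrix(
            [ind for ind, k in zip(geno.individuals, keep) if k],
            geno.genmap,
            geno.codes[keep],
        )
        P = _probability_grid(sub, positions)  # (n, G, 2)
    else:
        P = _prob_grid[keep]
    l0 = _null_loglik(y)
    l1, mu, sigma2 = _em_core(np.swapaxes(P, 0, 1), y, tol=tol, max_iter=max_iter)
    lod = (l1 - l0) / _LN10
    return LodCurve(
        chromosome=geno.genmap.chromosome,
        position_bp=positions,
        position_cm=geno.genmap.cm_at(positions),
        lod=lod,
        mu_nn=mu[:, 0],
        mu_nb=mu[:, 1],
        sigma=np.sqrt(sigma2),
        trait=trait,
    )


def marker_regression_lod(genotypes, pheno) -> float:
    """Closed-form LOD at a fully typed marker: (n/2) log10(RSS0 / RSS1).

    Independent of the EM path; used as an oracle for the scan.
    """
    g = np.asarray(genotypes)
    y = np.asarray(pheno, dtype=float)
    if np.any(g == MISSING):
        raise ValueError("marker must be fully typed")
    n = y.size
    rss0 = float(np.sum((y - y.mean()) ** 2))
    rss1 = 0.0
    for cls in (NN, NB):
        sel = y[g == cls]
        if sel.size:
            rss1 += float(np.sum((sel - sel.mean()) ** 2))
    if rss1 <= 0:
        raise ValueError("degenerate fit: zero residual variance")
    return 0.5 * n * np.log10(rss0 / rss1)


# ---------------------------------------------------------------------------
# permutation threshold


def permutation_threshold(
    geno: GenotypeMatrix,
    pheno,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed=0,
    step_bp: int = 500_000,
) -> PermutationNull:
    """Genome-wide significance threshold by phenotype permutation.

    The phenotype vector is shuffled against the genotype rows, the full
    scan repeated, and the genome-wide maximum LOD recorded; the threshold
    is the empirical (1 - alpha) quantile (type-7) of the maxima.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is low for quantile estimation", RuntimeWarning,
            stacklevel=2,
        )
    y = np.asarray(pheno, dtype=float)
    keep = ~np.isnan(y)
    y = y[keep]
    sub = GenotypeMatrix(
        [ind for ind, k in zip(geno.individuals, keep) if k],
        geno.genmap,
        geno.codes[keep],
    )
    positions = _scan_grid(geno.genmap, step_bp)
    P = np.swapaxes(_probability_grid(sub, positions), 0, 1)  # (G, n, 2)
    l0 = _null_loglik(y)

    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        l1, _, _ = _em_core(P, yp)
        maxima[b] = float(np.max((l1 - l0) / _LN10))
    return PermutationNull(max_lod=maxima, alpha=alpha)


# ---------------------------------------------------------------------------
# peak effect summaries


def peak_effects(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    marker: str,
    trait: str,
    groups=None,
) -> PeakEffectSummary:
    """Per-genotype-class summaries and tests at a peak marker.

    Two classes: Welch two-sided t-test.  Three or more (e.g. congenic
    B/B vs N/B vs N/N): one-way ANOVA followed by pairwise Welch t-tests
    with Bonferroni adjustment.  Classes with fewer than 2 members are
    excluded with a warning.
    """
    y = pheno.trait(trait).to_numpy(dtype=float) if isinstance(pheno, PhenotypeTable) \
        else np.asarray(pheno, dtype=float)
    if groups is None:
        codes = geno.column(marker)
        labels = np.array([GENOTYPE_LABELS[c] for c in codes])
        labels[codes == MISSING] = ""
    else:
        labels = np.asarray(groups, dtype=object).astype(str)
    ok = (labels != "") & ~np.isnan(y)
    y, labels = y[ok], labels[ok]

    stats_rows = {}
    samples = {}
    for cls in sorted(set(labels)):
        vals = y[labels == cls]
        if vals.size < 2:
            warnings.warn(
                f"class {cls!r} has {vals.size} member(s); excluded",
                RuntimeWarning, stacklevel=2,
            )
            continue
        samples[cls] = vals
        stats_rows[cls] = {
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "sem": float(stats.sem(vals)),
        }
    if len(samples) < 2:
        raise ValueError("need at least two genotype classes with >= 2 members")

    classes = list(samples)
    p_values = {}
    if len(classes) == 2:
        test = "welch-t"
        a, b = (samples[c] for c in classes)
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            p = 1.0 if np.isnan(p) else p
        p_values[f"{classes[0]} vs {classes[1]}"] = p
    else:
        test = "anova-bonferroni"
        p_values["anova"] = float(stats.f_oneway(*samples.values()).pvalue)
        pairs = [
            (classes[i], classes[j])
            for i in range(len(classes))
            for j in range(i + 1, len(classes))
        ]
        m = len(pairs)
        for ca, cb in pairs:
            praw = float(stats.ttest_ind(samples[ca], samples[cb], equal_var=False).pvalue)
            praw = 1.0 if np.isnan(praw) else praw
            p_values[f"{ca} vs {cb}"] = min(1.0, m * praw)

    idx = geno.genmap.index_of(marker)
    return PeakEffectSummary(
        marker=marker,
        position_bp=int(geno.genmap.position_bp[idx]),
        trait=trait,
        class_stats=pd.DataFrame(stats_rows).T.astype({"n": int}),
        test=test,
        p_values=p_values,
    )
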