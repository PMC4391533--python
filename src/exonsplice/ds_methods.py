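"""Per-gene differential-splicing scores and tests.

Six detectors over a two-condition :class:`~exonsplice.core_model.GeneBlock`:

* ``klas``   - quantile-ratio-weighted symmetrized Kullback-Leibler
  divergence between the per-condition probability distributions of exon
  deviations from gene expression (score; higher = more evidence of DS).
* ``si``     - splicing index: between-condition difference of
  gene-normalized exon expression; gene score = max |SI| over exons.
* ``arh``    - entropy of a probability distribution over exons' splicing
  deviations, corrected by its theoretical maximum and weighted by the
  deviation spread (score).
* ``midas``  - per-exon location test (one-way ANOVA / two-sample t-test)
  on gene-normalized values; gene p = Bonferroni-corrected min exon p.
* ``pac``    - exon-to-gene Pearson correlation deficit (score).
* ``anosva`` - F-test of the exon x condition interaction in a two-way
  fixed-effects linear model of log2 expression.

KLAS, SI, ARH and PAC emit heuristic scores; MIDAS and ANOSVA emit
p-values natively.  :func:`run_method` attaches Monte Carlo permutation
p-values to the score methods so all six can be classified at a common
significance level.

All expression is log2 scale; exponentials and logarithms in the KLAS and
ARH formulas are base 2 throughout, so deviations of d log2 units weigh an
exon by 2**d (linear-scale fold change).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_model import ExonExpressionSet, GeneBlock, MethodResult

logger = logging.getLogger(__name__)

METHODS = ("klas", "si", "arh", "midas", "pac", "anosva")
SCORE_METHODS = ("klas", "si", "arh", "pac")
PVALUE_METHODS = ("midas", "anosva")

Q_MODES = ("quotient_linear", "iqr_log", "fixed_1")

#: published decision cutoffs for the score methods (log2 |SI|; ARH score)
SI_CUTOFF_DEFAULT = 1.5
ARH_CUTOFF_DEFAULT = 0.03


# ---------------------------------------------------------------------------
# building blocks

def condition_profile(block: GeneBlock, condition: str) -> np.ndarray:
    """Per-exon mean log2 expression over one condition's samples.

    The gene-level summary for the condition is the mean of these per-exon
    means (mean of the returned vector).
    """
    mask = block.condition_mask(condition)
    if mask.sum() < 2:
        raise ValueError(
            f"condition {condition!r} has {int(mask.sum())} sample(s); >= 2 required"
        )
    return block.matrix[:, mask].mean(axis=1)


def exon_probability_distribution(d: np.ndarray) -> np.ndarray:
    """Turn per-exon deviations into a probability distribution.

    Softmax base 2: p_e = 2**d_e / sum_e 2**d_e.  Strictly positive, sums
    to one, and invariant under adding a constant to all deviations.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("KLAS requires >= 2 exons")
    if not np.isfinite(d).all():
        raise ValueError("deviations must be finite")
    return _softmax2(d[:, None])[:, 0]


def _softmax2(d: np.ndarray) -> np.ndarray:
    """Column-wise base-2 softmax of an (exons, k) deviation array."""
    w = np.exp2(d - d.max(axis=0, keepdims=True))
    return w / w.sum(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# mean-based score kernels
#
# KLAS, SI and ARH depend on the data only through the per-condition exon
# means.  The kernels below take (exons, k) arrays of such means - k
# parallel label assignments at once - which lets the permutation test
# score hundreds of relabelings in one vectorized call through exactly the
# code path used for the observed labels.

def _klas_from_means(m1: np.ndarray, m2: np.ndarray, q_mode: str) -> np.ndarray:
    d1 = m1 - m1.mean(axis=0, keepdims=True)
    d2 = m2 - m2.mean(axis=0, keepdims=True)
    p1 = _softmax2(d1)
    p2 = _softmax2(d2)
    q1 = _q_weight(d1, q_mode)
    q2 = _q_weight(d2, q_mode)
    kl12 = (p1 * np.log2(p1 / p2)).sum(axis=0)
    kl21 = (p2 * np.log2(p2 / p1)).sum(axis=0)
    return q1 * kl12 + q2 * kl21


def _q_weight(d: np.ndarray, q_mode: str) -> np.ndarray:
    """Within-condition spread weight from the deviation quantiles.

    ``quotient_linear`` (default) takes the 0.75/0.25 quantile quotient of
    the linear-scale weights 2**d, which is always positive and >= 1;
    ``iqr_log`` is the plain interquartile range of d (the literal
    quotient of log-scale quantiles is undefined when a quantile is zero
    or the two quantiles differ in sign); ``fixed_1`` disables weighting.
    """
    if q_mode == "fixed_1":
        return np.ones(d.shape[1])
    if q_mode == "iqr_log":
        q75, q25 = np.quantile(d, [0.75, 0.25], axis=0)
        return q75 - q25
    if q_mode == "quotient_linear":
        lin = np.exp2(d)
        q75, q25 = np.quantile(lin, [0.75, 0.25], axis=0)
        return q75 / q25
    raise ValueError(f"unknown q_mode {q_mode!r}; valid: {Q_MODES}")


def _si_from_means(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """Per-exon splicing index for each column of condition means."""
    return (m1 - m1.mean(axis=0, keepdims=True)) - (m2 - m2.mean(axis=0, keepdims=True))


def _si_score_from_means(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    return np.abs(_si_from_means(m1, m2)).max(axis=0)


def _arh_from_means(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    si = _si_from_means(m1, m2)
    s = si - np.median(si, axis=0, keepdims=True)
    q = _softmax2(s)
    entropy = -(q * np.log2(q)).sum(axis=0)
    q75, q25 = np.quantile(s, [0.75, 0.25], axis=0)
    weight = q75 - q25
    n_exons = m1.shape[0]
    return weight * (1.0 - entropy / np.log2(n_exons))


_MEAN_KERNELS = {
    "si": _si_score_from_means,
    "arh": _arh_from_means,
}


def mean_based_score_fn(method: str, q_mode: str = "quotient_linear"):
    """Kernel mapping two (exons, k) condition-mean arrays to k scores."""
    if method == "klas":
        return lambda m1, m2: _klas_from_means(m1, m2, q_mode)
    try:
        return _MEAN_KERNELS[method]
    except KeyError:
        raise ValueError(f"no mean-based kernel for method {method!r}") from None


def _two_condition_means(block: GeneBlock) -> tuple[np.ndarray, np.ndarray]:
    c1, c2 = _two_conditions(block)
    return (
        condition_profile(block, c1)[:, None],
        condition_profile(block, c2)[:, None],
    )


def _two_conditions(block: GeneBlock) -> tuple[str, str]:
    conds = block.conditions
    if len(conds) != 2:
        raise ValueError(
            f"gene {block.gene_id}: expected 2 conditions, found {len(conds)}"
        )
    # fixed lexicographic orientation: ARH and per-exon SI are orientation
    # dependent, so the reference condition must not hinge on column order
    c1, c2 = sorted(conds)
    return c1, c2


# ---------------------------------------------------------------------------
# KLAS

@dataclass(frozen=True)
class KlasIntermediate:
    """All intermediate quantities of one KLAS evaluation."""

    d_c1: np.ndarray
    d_c2: np.ndarray
    p_c1: np.ndarray
    p_c2: np.ndarray
    q_c1: float
    q_c2: float
    kl: float


def klas_intermediate(block: GeneBlock, q_mode: str = "quotient_linear") -> KlasIntermediate:
    if block.n_exons < 2:
        raise ValueError("KLAS requires >= 2 exons")
    m1, m2 = _two_condition_means(block)
    d1 = (m1 - m1.mean(axis=0, keepdims=True))[:, 0]
    d2 = (m2 - m2.mean(axis=0, keepdims=True))[:, 0]
    return KlasIntermediate(
        d_c1=d1,
        d_c2=d2,
        p_c1=exon_probability_distribution(d1),
        p_c2=exon_probability_distribution(d2),
        q_c1=float(_q_weight(d1[:, None], q_mode)[0]),
        q_c2=float(_q_weight(d2[:, None], q_mode)[0]),
        kl=float(_klas_from_means(m1, m2, q_mode)[0]),
    )


def klas_score(block: GeneBlock, q_mode: str = "quotient_linear") -> float:
    """Quantile-ratio-weighted symmetrized KL divergence between conditions.

    Each condition's per-exon deviations from gene expression are turned
    into a probability distribution (base-2 softmax); the two distributions
    are compared by a symmetrized Kullback-Leibler divergence whose halves
    are weighted by the within-condition deviation spread Q.  Zero iff the
    two distributions coincide (for positive Q); symmetric in the
    conditions; higher = more evidence of differential splicing.
    """
    if block.n_exons < 2:
        raise ValueError("KLAS requires >= 2 exons")
    m1, m2 = _two_condition_means(block)
    return float(_klas_from_means(m1, m2, q_mode)[0])


# ---------------------------------------------------------------------------
# comparator scores

def splicing_index(block: GeneBlock) -> tuple[np.ndarray, float]:
    """Per-exon splicing index and the gene-level score max |SI|.

    SI_e = (x_{e,c1} - gene_c1) - (x_{e,c2} - gene_c2) on the log2 scale:
    the between-condition difference of gene-normalized exon expression.
    """
    m1, m2 = _two_condition_means(block)
    si = _si_from_means(m1, m2)[:, 0]
    return si, float(np.abs(si).max())


def arh_score(block: GeneBlock) -> float:
    """Entropy-based splicing deviation score.

    Per-exon deviations s_e = SI_e - median(SI) are softmax-transformed
    into probabilities; the score is IQR(s) * (1 - H(q)/log2(E)), i.e. the
    deviation spread times one minus the entropy relative to its maximum.
    Zero when all exons behave alike.
    """
    if block.n_exons < 2:
        raise ValueError("ARH requires >= 2 exons")
    m1, m2 = _two_condition_means(block)
    return float(_arh_from_means(m1, m2)[0])


def pac_score(block: GeneBlock) -> float:
    """Correlation-deficit score: 1 - min over exons of corr(exon, gene).

    For each exon, the Pearson correlation across *all* samples between the
    exon's log2 values and the per-sample gene-level values (mean over
    exons).  Proportional exons correlate perfectly (score 0); a spliced
    exon decouples from the gene and drags the minimum correlation down.
    Exons with zero variance are skipped.
    """
    if block.n_exons < 2:
        raise ValueError("PAC requires >= 2 exons")
    if block.n_samples < 3:
        raise ValueError("PAC requires >= 3 samples")
    x = block.matrix
    gene = x.mean(axis=0)
    gc = gene - gene.mean()
    g_ss = (gc**2).sum()
    if g_ss == 0:
        raise ValueError(f"gene {block.gene_id}: gene-level values have zero variance")
    xc = x - x.mean(axis=1, keepdims=True)
    e_ss = (xc**2).sum(axis=1)
    valid = e_ss > 0
    if not valid.any():
        raise ValueError(f"gene {block.gene_id}: all exons have zero variance")
    if not valid.all():
        logger.warning(
            "gene %s: skipping %d zero-variance exon(s) in PAC",
            block.gene_id,
            int((~valid).sum()),
        )
    r = (xc[valid] @ gc) / np.sqrt(e_ss[valid] * g_ss)
    return float(1.0 - r.min())


# ---------------------------------------------------------------------------
# native p-value methods

def midas_pvalue(block: GeneBlock) -> tuple[np.ndarray, float]:
    """Per-exon location test on gene-normalized values; Bonferroni gene p.

    Each sample's exon values are centered by that sample's gene-level
    value (mean over exons); each exon then gets a two-sided equal-variance
    two-sample t-test (equivalently one-way ANOVA) between conditions.  The
    gene p-value is min_e(p_e * E) capped at 1.  Exons whose between-group
    difference is zero or whose variance vanishes in both groups yield
    p = 1.
    """
    c1, c2 = _two_conditions(block)
    x = block.matrix
    norm = x - x.mean(axis=0, keepdims=True)  # per-sample gene-level centering
    a = norm[:, block.condition_mask(c1)]
    b = norm[:, block.condition_mask(c2)]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("MIDAS requires >= 2 samples per condition")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=True)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        # zero pooled variance: p = 1 for equal means, 0 for separated means
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    gene_p = float(min(1.0, p.min() * block.n_exons))
    return p, gene_p


def anosva_pvalue(block: GeneBlock) -> float:
    """F-test of the exon x condition interaction.

    Fits the two-way fixed-effects model
    ``log2 expression ~ exon + condition + exon:condition`` on the
    long-form data and tests the interaction block by model comparison.
    Because every exon is measured in every sample, cell counts are
    proportional, so the additive least-squares fit has the closed form
    exon margin + condition margin - grand mean.
    """
    c1, c2 = _two_conditions(block)
    x = block.matrix
    n_exons = x.shape[0]
    if n_exons < 2:
        raise ValueError("ANOSVA requires >= 2 exons")
    mask1 = block.condition_mask(c1)
    mask2 = block.condition_mask(c2)
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(
            "ANOSVA requires >= 2 samples per condition (saturated design otherwise)"
        )
    groups = (x[:, mask1], x[:, mask2])
    sizes = (n1, n2)
    n_total = x.size

    sse_full = 0.0
    sse_lof = 0.0  # lack-of-fit of the additive model at the cell means
    grand = x.mean()
    exon_margin = x.mean(axis=1)
    for g, n_c in zip(groups, sizes):
        cell = g.mean(axis=1)  # per-exon mean within this condition
        sse_full += ((g - cell[:, None]) ** 2).sum()
        additive = exon_margin + g.mean() - grand
        sse_lof += n_c * ((cell - additive) ** 2).sum()

    df_inter = n_exons - 1  # (E-1) * (2-1)
    df_resid = n_total - 2 * n_exons
    if df_resid <= 0:
        raise ValueError("ANOSVA design is saturated; more samples required")
    if sse_full == 0.0:
        # no residual variance: p=1 unless the interaction itself is nonzero
        return 1.0 if sse_lof == 0.0 else 0.0
    f = (sse_lof / df_inter) / (sse_full / df_resid)
    return float(stats.f.sf(f, df_inter, df_resid))


# ---------------------------------------------------------------------------
# batch driver

_MIN_EXONS = {"klas": 2, "si": 1, "arh": 2, "midas": 1, "pac": 2, "anosva": 2}


def run_method(
    dataset: ExonExpressionSet,
    method: str,
    perm_config=None,
    q_mode: str = "quotient_linear",
) -> MethodResult:
    """Apply one method gene-by-gene over a dataset.

    Score methods (klas, si, arh, pac) return scores, plus Monte Carlo
    permutation p-values when ``perm_config`` (a
    :class:`~exonsplice.permutation.PermutationConfig`) is given; midas and
    anosva return p-values only.  Genes failing a method's preconditions
    are skipped with a logged reason and carry NaN entries.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; valid: {list(METHODS)}")

    n = dataset.n_genes
    scores = np.full(n, np.nan) if method in SCORE_METHODS else None
    pvals = np.full(n, np.nan) if (method in PVALUE_METHODS or perm_config) else None
    skipped: dict[str, str] = {}

    from .permutation import permutation_pvalue_fast  # local import, cycle-free

    for i, gene_id in enumerate(dataset.gene_ids):
        block = dataset.gene_block(gene_id)
        try:
            if block.n_exons < _MIN_EXONS[method]:
                raise ValueError(
                    f"{method} requires >= {_MIN_EXONS[method]} exons, gene has {block.n_exons}"
                )
            if method == "klas":
                scores[i] = klas_score(block, q_mode=q_mode)
            elif method == "si":
                scores[i] = splicing_index(block)[1]
            elif method == "arh":
                scores[i] = arh_score(block)
            elif method == "pac":
                scores[i] = pac_score(block)
            elif method == "midas":
                pvals[i] = midas_pvalue(block)[1]
            elif method == "anosva":
                pvals[i] = anosva_pvalue(block)
            if method in SCORE_METHODS and perm_config is not None:
                pvals[i] = permutation_pvalue_fast(method, block, perm_config, q_mode=q_mode)
        except ValueError as exc:
            skipped[gene_id] = str(exc)
            logger.info("gene %s skipped by %s: %s", gene_id, method, exc)

    return MethodResult(
        method=method, gene_ids=list(dataset.gene_ids), score=scores, p_value=pvals, skipped=skipped
    )
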