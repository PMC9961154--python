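"""Circadian gene-set analysis for a 2x2 (genotype x time-of-day) design.

The design has four groups — wild-type morning (WT_M), wild-type night
(WT_N), mutant morning (MUT_M), mutant night (MUT_N) — with replicated
bulk RNA-seq counts. The pipeline:

1. FPKM normalization and the expressed-gene filter (FPKM > 0.1 in every
   sample of at least one group).
2. Differential expression per contrast, thresholded at fold-change >= 1.5
   and BH-adjusted p <= 0.05. External per-gene statistics tables (e.g.,
   from a negative-binomial GLM tool) can be thresholded directly; for
   self-contained synthetic runs a stand-in two-sample test on
   log2(FPKM + 1) is provided (moderated pooled-variance t by default).
3. Contrast set algebra: U1/D1 (mutant vs WT, morning), U2/D2 (mutant vs
   WT, night), U3/D3 (WT night vs morning), U4/D4 (mutant night vs
   morning). Night-preferring mutation-affected genes GS1 = U3 & D2 (up at
   night in WT, blunted in the mutant); morning-preferring affected genes
   GS2 = D3 & U2 (down at night in WT, attenuated in the mutant).
4. G-test (likelihood-ratio test of independence) for enrichment of
   mutation-affected genes among circadian genes.

A negative-binomial count generator with planted circadian and
genotype-interaction effects provides ground truth for end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GROUPS",
    "CONTRASTS",
    "ExpressionMatrix",
    "ContrastResult",
    "ContrastSets",
    "GTestResult",
    "PlantedTruth",
    "compute_fpkm",
    "filter_expressed",
    "call_degs",
    "derive_circadian_sets",
    "g_test",
    "simulate_counts",
]

GROUPS = ("WT_M", "WT_N", "MUT_M", "MUT_N")

#: contrast name -> (numerator group, denominator group)
CONTRASTS = {
    "M_mut_vs_wt": ("MUT_M", "WT_M"),
    "N_mut_vs_wt": ("MUT_N", "WT_N"),
    "WT_N_vs_M": ("WT_N", "WT_M"),
    "MUT_N_vs_M": ("MUT_N", "MUT_M"),
}

#: contrast -> (up set, down set) labels in the U/D nomenclature
CONTRAST_SET_NAMES = {
    "M_mut_vs_wt": ("U1", "D1"),
    "N_mut_vs_wt": ("U2", "D2"),
    "WT_N_vs_M": ("U3", "D3"),
    "MUT_N_vs_M": ("U4", "D4"),
}

DEFAULT_GS_EXPRESSIONS = {"GS1": ("U3", "D2"), "GS2": ("D3", "U2")}

EXPRESSED_FPKM_MIN = 0.1
DEG_FC_MIN = 1.5
DEG_PADJ_MAX = 0.05


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples expression values with design metadata.

    ``values`` is a genes-by-samples DataFrame (gene ids as index);
    ``groups`` maps each sample (column) to one of :data:`GROUPS`;
    ``gene_lengths`` (bp) and ``library_sizes`` (total mapped fragments)
    are needed for FPKM computation from counts.
    """

    values: pd.DataFrame
    groups: pd.Series
    gene_lengths: pd.Series | None = None
    library_sizes: pd.Series | None = None
    units: str = "counts"

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be >= 0")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)[:5]}")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}; expected {GROUPS}")

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


def compute_fpkm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """FPKM = count * 1e9 / (gene length [bp] * total mapped fragments).

    Library sizes default to per-sample count sums when not supplied.
    """
    if matrix.units != "counts":
        raise ValueError("compute_fpkm expects a counts matrix")
    if matrix.gene_lengths is None:
        raise ValueError("gene_lengths required for FPKM")
    lengths = matrix.gene_lengths.reindex(matrix.values.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    lib = (
        matrix.library_sizes
        if matrix.library_sizes is not None
        else matrix.values.sum(axis=0)
    )
    lib = lib.reindex(matrix.values.columns)
    if lib.isna().any() or (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    fpkm = matrix.values * 1e9
    fpkm = fpkm.div(lengths, axis=0).div(lib, axis=1)
    return ExpressionMatrix(
        values=fpkm,
        groups=matrix.groups,
        gene_lengths=matrix.gene_lengths,
        library_sizes=lib,
        units="fpkm",
    )


def filter_expressed(
    matrix: ExpressionMatrix, threshold: float = EXPRESSED_FPKM_MIN
) -> set[str]:
    """Expressed genes: FPKM strictly above threshold in *every* sample of
    at least one experimental group."""
    if matrix.units != "fpkm":
        raise ValueError("filter_expressed expects an FPKM matrix")
    keep = np.zeros(len(matrix.values), dtype=bool)
    for g in GROUPS:
        cols = matrix.samples_of(g)
        if not cols:
            raise ValueError(f"group {g} has no samples")
        keep |= (matrix.values[cols] > threshold).all(axis=1).to_numpy()
    return set(matrix.values.index[keep])


@dataclass(frozen=True)
class ContrastResult:
    """Per-gene statistics for one contrast plus the DEG calls.

    ``table`` has columns fold_change (linear, numerator/denominator),
    p_value, p_adj, and direction ("up"/"down"/"ns").
    """

    contrast: str
    table: pd.DataFrame
    fc_min: float = DEG_FC_MIN
    padj_max: float = DEG_PADJ_MAX

    @property
    def up(self) -> set[str]:
        return set(self.table.index[self.table["direction"] == "up"])

    @property
    def down(self) -> set[str]:
        return set(self.table.index[self.table["direction"] == "down"])

    @property
    def degs(self) -> set[str]:
        return self.up | self.down


def _direction(fc: np.ndarray, padj: np.ndarray, fc_min: float, padj_max: float) -> np.ndarray:
    sig = padj <= padj_max
    out = np.full(fc.shape, "ns", dtype=object)
    out[sig & (fc >= fc_min)] = "up"
    out[sig & (fc <= 1.0 / fc_min)] = "down"
    return out


def threshold_degs(
    table: pd.DataFrame,
    contrast: str,
    fc_min: float = DEG_FC_MIN,
    padj_max: float = DEG_PADJ_MAX,
) -> ContrastResult:
    """Apply the DEG thresholds to an externally computed statistics table.

    ``table`` needs columns ``fold_change`` (linear) and ``p_adj``; other
    columns are preserved.
    """
    t = table.copy()
    if not {"fold_change", "p_adj"} <= set(t.columns):
        raise ValueError("table needs fold_change and p_adj columns")
    t["direction"] = _direction(
        t["fold_change"].to_numpy(float), t["p_adj"].to_numpy(float), fc_min, padj_max
    )
    return ContrastResult(contrast=contrast, table=t, fc_min=fc_min, padj_max=padj_max)


def call_degs(
    matrix: ExpressionMatrix,
    contrast: str,
    genes: Iterable[str] | None = None,
    fc_min: float = DEG_FC_MIN,
    padj_max: float = DEG_PADJ_MAX,
    method: str = "moderated",
) -> ContrastResult:
    """Stand-in differential-expression call on log2(FPKM + 1).

    ``method`` selects the two-sample test: "moderated" (pooled-variance t
    with empirical-Bayes shrinkage of per-gene variances toward their
    median, prior df 10 — the default, standard practice at small n),
    "welch", or "student". Fold-change is the ratio of linear group mean
    FPKM. p-values are BH-adjusted across the tested genes. This is a
    declared stand-in for a negative-binomial GLM fit, intended for
    synthetic, self-contained runs.
    """
    if matrix.units != "fpkm":
        raise ValueError("call_degs expects an FPKM matrix")
    if contrast not in CONTRASTS:
        raise KeyError(f"unknown contrast {contrast!r}; choose from {list(CONTRASTS)}")
    num_g, den_g = CONTRASTS[contrast]
    a_cols, b_cols = matrix.samples_of(num_g), matrix.samples_of(den_g)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each side of a contrast needs >= 2 replicates")
    vals = matrix.values if genes is None else matrix.values.loc[sorted(genes)]
    A = vals[a_cols].to_numpy(float)
    B = vals[b_cols].to_numpy(float)
    la, lb = np.log2(A + 1.0), np.log2(B + 1.0)
    na, nb = la.shape[1], lb.shape[1]

    if method == "welch":
        _, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    elif method == "student":
        _, p = stats.ttest_ind(la, lb, axis=1, equal_var=True)
    elif method == "moderated":
        va = la.var(axis=1, ddof=1)
        vb = lb.var(axis=1, ddof=1)
        df = na + nb - 2
        s2 = ((na - 1) * va + (nb - 1) * vb) / df
        d0, s0 = 10.0, float(np.median(s2))
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        tstat = (la.mean(axis=1) - lb.mean(axis=1)) / se
        p = 2.0 * stats.t.sf(np.abs(tstat), d0 + df)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = np.nan_to_num(np.asarray(p, dtype=float), nan=1.0)
    padj = stats.false_discovery_control(p, method="bh")
    eps = 1e-9
    fc = (A.mean(axis=1) + eps) / (B.mean(axis=1) + eps)
    table = pd.DataFrame(
        {
            "fold_change": fc,
            "log2_fold_change": np.log2(fc),
            "p_value": p,
            "p_adj": padj,
            "direction": _direction(fc, padj, fc_min, padj_max),
        },
        index=vals.index,
    )
    return ContrastResult(contrast=contrast, table=table, fc_min=fc_min, padj_max=padj_max)


@dataclass(frozen=True)
class ContrastSets:
    """U/D gene sets for the four contrasts and the derived GS1/GS2 classes.

    GS1 (night-preferring, mutation-affected) and GS2 (morning-preferring,
    mutation-affected) default to U3 & D2 and D3 & U2; the set expressions
    used are recorded in ``gs_expressions``.
    """

    sets: dict[str, set[str]]
    gs_expressions: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_GS_EXPRESSIONS)
    )

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __post_init__(self) -> None:
        for u, d in CONTRAST_SET_NAMES.values():
            if self.sets[u] & self.sets[d]:
                raise ValueError(f"{u} and {d} overlap")


def derive_circadian_sets(
    contrasts: Mapping[str, ContrastResult],
    gs_expressions: Mapping[str, tuple[str, str]] | None = None,
) -> ContrastSets:
    """Build U1..D4 and the mutation-affected circadian classes GS1/GS2.

    ``contrasts`` must supply all four named contrasts over the same gene
    universe. ``gs_expressions`` maps each GS name to a pair of U/D set
    names to intersect (defaults: GS1 = U3 & D2, GS2 = D3 & U2).
    """
    missing = set(CONTRASTS) - set(contrasts)
    if missing:
        raise ValueError(f"missing contrasts: {sorted(missing)}")
    universes = {frozenset(c.table.index) for c in contrasts.values()}
    if len(universes) != 1:
        raise ValueError("contrasts computed over different gene universes")
    sets: dict[str, set[str]] = {}
    for cname, (u_name, d_name) in CONTRAST_SET_NAMES.items():
        sets[u_name] = contrasts[cname].up
        sets[d_name] = contrasts[cname].down
    exprs = dict(gs_expressions or DEFAULT_GS_EXPRESSIONS)
    for gs, (a, b) in exprs.items():
        sets[gs] = sets[a] & sets[b]
    return ContrastSets(sets=sets, gs_expressions=exprs)


# ---------------------------------------------------------------------------
# G-test of independence


@dataclass(frozen=True)
class GTestResult:
    observed: np.ndarray
    expected: np.ndarray
    g: float
    df: int
    p_value: float
    williams_corrected: bool

    def __post_init__(self) -> None:
        if self.g < -1e-12:
            raise ValueError("G must be >= 0")


def g_test(table: np.ndarray | Iterable[Iterable[int]], williams_correction: bool = False) -> GTestResult:
    """Likelihood-ratio (G) test of independence for a 2x2 table.

    G = 2 * sum O * ln(O/E) with zero observed cells contributing 0 and
    expected counts from the margins; df = 1; p is the upper chi-square
    tail. The optional Williams correction divides G by
    q = 1 + (N/r1 + N/r2 - 1)(N/c1 + N/c2 - 1) / (6N).
    """
    O = np.asarray(table, dtype=float)
    if O.shape != (2, 2):
        raise ValueError("g_test expects a 2x2 table")
    if np.any(O < 0) or not np.allclose(O, np.round(O)):
        raise ValueError("counts must be nonnegative integers")
    rows = O.sum(axis=1)
    cols = O.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("every row and column margin must be > 0")
    N = O.sum()
    E = np.outer(rows, cols) / N
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(O > 0, O * np.log(O / E), 0.0)
    g = 2.0 * float(terms.sum())
    corrected = False
    if williams_correction:
        q = 1.0 + (np.sum(N / rows) - 1.0) * (np.sum(N / cols) - 1.0) / (6.0 * N)
        g /= q
        corrected = True
    g = max(g, 0.0)
    return GTestResult(
        observed=O,
        expected=E,
        g=g,
        df=1,
        p_value=float(stats.chi2.sf(g, 1)),
        williams_corrected=corrected,
    )


def enrichment_table(
    expressed: set[str], circadian: set[str], affected: set[str]
) -> np.ndarray:
    """2x2 table of expressed genes: (circadian yes/no) x (affected yes/no)."""
    circ = circadian & expressed
    aff = affected & expressed
    a = len(circ & aff)
    b = len(circ - aff)
    c = len(aff - circ)
    d = len(expressed - circ - aff)
    return np.array([[a, b], [c, d]])


# ---------------------------------------------------------------------------
# Synthetic counts


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of :func:`simulate_counts`."""

    circadian_genes: set[str]  # morning-preferring (down at night in both genotypes)
    affected_genes: set[str]  # subset with attenuated night downregulation in the mutant
    params: dict


def simulate_counts(
    n_genes: int = 2000,
    n_planted_circadian: int = 130,
    n_planted_affected: int = 30,
    circadian_fold: float = 3.0,
    attenuation_fold: float = 2.0,
    dispersion: float = 0.1,
    n_reps: int = 4,
    seed: int = 0,
    mean_log10_range: tuple[float, float] = (0.0, 4.0),
    length_range_bp: tuple[int, int] = (500, 5000),
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Negative-binomial counts for the 4-group design with planted effects.

    Baseline means are log-uniform over ``10**mean_log10_range``. Planted
    circadian genes are morning-preferring: their night mean is divided by
    ``circadian_fold`` in both genotypes. The first ``n_planted_affected``
    of them additionally have their mutant-night mean multiplied by
    ``attenuation_fold`` (the night downregulation is attenuated by the
    mutation), making them the ground-truth GS2 class. Variance follows
    mu + dispersion * mu**2; dispersion 0 gives Poisson counts.
    """
    if n_planted_affected > n_planted_circadian:
        raise ValueError("affected genes must be a subset of circadian genes")
    if n_planted_circadian > n_genes:
        raise ValueError("planted genes exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    base = 10.0 ** rng.uniform(*mean_log10_range, n_genes)
    lengths = rng.integers(length_range_bp[0], length_range_bp[1] + 1, n_genes)
    circadian = genes[:n_planted_circadian]
    affected = genes[:n_planted_affected]

    mu = {g: base.copy() for g in GROUPS}
    circ_idx = np.arange(n_planted_circadian)
    aff_idx = np.arange(n_planted_affected)
    mu["WT_N"][circ_idx] /= circadian_fold
    mu["MUT_N"][circ_idx] /= circadian_fold
    mu["MUT_N"][aff_idx] *= attenuation_fold

    cols = []
    data = []
    groups = {}
    for g in GROUPS:
        for r in range(n_reps):
            name = f"{g}_r{r + 1}"
            cols.append(name)
            groups[name] = g
            m = mu[g]
            if dispersion > 0:
                r_nb = 1.0 / dispersion
                p_nb = r_nb / (r_nb + m)
                data.append(rng.negative_binomial(r_nb, p_nb))
            else:
                data.append(rng.poisson(m))
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    matrix = ExpressionMatrix(
        values=values,
        groups=pd.Series(groups),
        gene_lengths=pd.Series(lengths, index=genes),
        units="counts",
    )
    truth = PlantedTruth(
        circadian_genes=set(circadian),
        affected_genes=set(affected),
        params={
            "n_genes": n_genes,
            "n_planted_circadian": n_planted_circadian,
            "n_planted_affected": n_planted_affected,
            "circadian_fold": circadian_fold,
            "attenuation_fold": attenuation_fold,
            "dispersion": dispersion,
            "n_reps": n_reps,
            "seed": seed,
        },
    )
    return matrix, truth
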