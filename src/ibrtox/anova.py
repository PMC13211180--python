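"""Factorial linear model with Type III (marginal) ANOVA.

The model regresses a z-scored response on categorical factors (treatment,
exposure day, biological matrix, biomarker type) and selected interactions
under sum-to-zero (deviation) contrasts. Each term's Type III sum of squares
is the increase in residual sum of squares when that term's columns are
removed from the otherwise full model:

    SS_T = RSS(model without T) - RSS(full model)
    F_T  = (SS_T / df_T) / (RSS_full / df_resid)

Under sum-to-zero coding this tests each term's marginal contribution with
all other terms (including interactions containing it) held in the model —
the 'car::Anova(type = 3)' convention. Treatment (dummy) coding is refused:
Type III sums of squares are contrast-dependent and dummy coding silently
answers a different question.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class DesignError(ValueError):
    """The design matrix cannot be built as requested."""


Term = tuple[str, ...]

#: Default term set: main effects plus the stated interactions.
def default_terms(factors: Sequence[str]) -> list[Term]:
    terms: list[Term] = [(f,) for f in factors]
    extra = [
        ("Treatment", "Day"),
        ("Treatment", "Biomarker"),
        ("Treatment", "Day", "Biomarker"),
    ]
    for t in extra:
        if all(f in factors for f in t):
            terms.append(t)
    return terms


def full_factorial_terms(factors: Sequence[str]) -> list[Term]:
    """All main effects and interactions of every order."""
    import itertools

    terms: list[Term] = []
    for r in range(1, len(factors) + 1):
        terms.extend(itertools.combinations(factors, r))
    return terms


def sum_coding(levels: Sequence) -> dict:
    """Deviation-coded rows: level i -> indicator row; last level -> all -1."""
    k = len(levels)
    rows = {}
    for i, lv in enumerate(levels):
        if i == k - 1:
            rows[lv] = -np.ones(k - 1)
        else:
            row = np.zeros(k - 1)
            row[i] = 1.0
            rows[lv] = row
    return rows


def build_design(
    data: pd.DataFrame,
    factors: Sequence[str],
    terms: Sequence[Term],
    contrasts: str = "sum",
) -> tuple[np.ndarray, dict[Term, slice], list[str]]:
    """Design matrix with intercept, sum-to-zero factor codings and products.

    Returns the matrix, a term -> column-slice map, and column names.
    Raises :class:`DesignError` for non-sum contrasts, a factor observed at a
    single level, or a rank-deficient design (naming the offending term).
    """
    if contrasts != "sum":
        raise DesignError(
            "Type III sums of squares require sum-to-zero contrasts; "
            f"{contrasts!r} coding would silently test different hypotheses"
        )
    level_maps = {}
    factor_cols = {}
    for f in factors:
        levels = sorted(pd.unique(data[f]).tolist(), key=str)
        if len(levels) < 2:
            raise DesignError(f"factor {f!r} is observed at a single level")
        level_maps[f] = levels
        coding = sum_coding(levels)
        factor_cols[f] = np.vstack([coding[v] for v in data[f]])
    blocks = [np.ones((len(data), 1))]
    names = ["Intercept"]
    term_slices: dict[Term, slice] = {}
    col = 1
    for term in terms:
        block = None
        for f in term:
            fc = factor_cols[f]
            if block is None:
                block = fc
            else:
                block = np.einsum("ij,ik->ijk", block, fc).reshape(len(data), -1)
        width = block.shape[1]
        term_slices[tuple(term)] = slice(col, col + width)
        blocks.append(block)
        names.extend([f"{':'.join(term)}[{i}]" for i in range(width)])
        col += width
    x = np.hstack(blocks)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # localise the deficiency for the error message
        running = blocks[0]
        for term, blk in zip(terms, blocks[1:]):
            cand = np.hstack([running, blk])
            if np.linalg.matrix_rank(cand) < cand.shape[1]:
                raise DesignError(f"design is rank-deficient at term {':'.join(term)!r}")
            running = cand
        raise DesignError("design is rank-deficient")
    return x, term_slices, names


def fit_least_squares(design: np.ndarray, response: np.ndarray):
    """Ordinary least squares on a full-rank design.

    Returns (coefficients, fitted, residuals, rss).
    """
    y = np.asarray(response, dtype=float)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DesignError("design matrix is rank-deficient")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    resid = y - fitted
    return coef, fitted, resid, float(resid @ resid)


class FactorialModel:
    """Fixed-effects factorial linear model (statsmodels-style).

    Parameters
    ----------
    data : DataFrame
        One row per observation; must contain ``response`` and every factor.
    response : str
        Name of the (typically z-scored) response column.
    factors : sequence of str
        Categorical factor columns.
    terms : sequence of tuples, optional
        Model terms as factor-name tuples. Defaults to all main effects plus
        the Treatment:Day, Treatment:Biomarker and Treatment:Day:Biomarker
        interactions (where those factors exist); pass
        ``full_factorial_terms(factors)`` for the saturated alternative.
    contrasts : str
        Only ``"sum"`` is accepted (see module docstring).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        factors: Sequence[str],
        terms: Sequence[Term] | None = None,
        contrasts: str = "sum",
    ):
        self.data = data.reset_index(drop=True)
        self.response = response
        self.factors = list(factors)
        self.terms = [tuple(t) for t in (terms if terms is not None else default_terms(factors))]
        for term in self.terms:
            for f in term:
                if (f,) not in self.terms:
                    raise DesignError(f"term {term} includes {f!r} without its main effect")
        self.contrasts = contrasts
        self.design, self.term_slices, self.column_names = build_design(
            self.data, self.factors, self.terms, contrasts
        )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str = "value", **kwargs):
        factors = kwargs.pop("factors", None)
        if factors is None:
            factors = [c for c in ("Treatment", "Day", "Matrix", "Biomarker") if c in data.columns]
        return cls(data, response, factors, **kwargs)

    def fit(self) -> "FactorialResults":
        y = self.data[self.response].to_numpy(dtype=float)
        coef, fitted, resid, rss = fit_least_squares(self.design, y)
        df_resid = len(y) - self.design.shape[1]
        rows = []
        for term in self.terms:
            sl = self.term_slices[term]
            keep = np.ones(self.design.shape[1], dtype=bool)
            keep[sl] = False
            _, _, _, rss_reduced = fit_least_squares(self.design[:, keep], y)
            ss = max(rss_reduced - rss, 0.0)
            df_t = sl.stop - sl.start
            f = (ss / df_t) / (rss / df_resid)
            p = float(stats.f.sf(f, df_t, df_resid))
            rows.append((":".join(term), ss, df_t, f, p))
        table = pd.DataFrame(rows, columns=["term", "sum_sq", "df", "F", "p"])
        table["df_den"] = df_resid
        return FactorialResults(self, coef, fitted, resid, rss, df_resid, table)


@dataclass
class FactorialResults:
    model: FactorialModel
    params: np.ndarray
    fittedvalues: np.ndarray
    resid: np.ndarray
    rss: float
    df_resid: int
    anova_table: pd.DataFrame

    def summary(self) -> str:
        lines = [
            "Factorial linear model, Type III ANOVA (sum-to-zero contrasts)",
            "=" * 64,
            f"observations: {len(self.fittedvalues)}   "
            f"residual df: {self.df_resid}   RSS: {self.rss:.4f}",
            "",
        ]
        tbl = self.anova_table.copy()
        tbl["p"] = tbl["p"].map(lambda v: f"{v:.3g}")
        lines.append(tbl.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


def type3_anova(
    data: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    terms: Sequence[Term] | None = None,
) -> pd.DataFrame:
    """One-call convenience returning just the Type III ANOVA table."""
    return FactorialModel(data, response, factors, terms).fit().anova_table
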