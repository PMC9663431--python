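"""Two-factor ANOVA machinery, vectorized over many response columns.

Both the single-unit selectivity screen (p-value time courses) and the
population information time course (omega-squared effect sizes) need the
same sum-of-squares decomposition applied to a trials x time-bins firing
rate matrix.  The factor layout is fixed across bins, so the design is
factored once and each evaluation costs a handful of matrix products.

Balanced layouts reduce to the classical decomposition; unbalanced
layouts use type-II sums of squares (each main effect adjusted for the
other, the interaction adjusted for both).  The two coincide when the
design is balanced.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["TwoWayAnova"]


class TwoWayAnova:
    """Pre-factored two-factor crossed layout with interaction.

    Parameters
    ----------
    a_labels, b_labels
        Per-trial factor levels (any hashable dtype), length ``n``.

    Raises
    ------
    ValueError
        If any cell of the A x B cross is empty, or there are no error
        degrees of freedom (``n <= A*B``).
    """

    def __init__(self, a_labels, b_labels):
        a_labels = np.asarray(a_labels)
        b_labels = np.asarray(b_labels)
        if a_labels.shape != b_labels.shape or a_labels.ndim != 1:
            raise ValueError("factor label vectors must be 1-D and equal length")
        self.a_levels, a = np.unique(a_labels, return_inverse=True)
        self.b_levels, b = np.unique(b_labels, return_inverse=True)
        self.n = a_labels.size
        A, B = self.a_levels.size, self.b_levels.size
        if A < 2 or B < 2:
            raise ValueError("each factor needs at least two observed levels")
        cell = a * B + b
        counts = np.bincount(cell, minlength=A * B)
        if np.any(counts == 0):
            raise ValueError("empty design cell: every A x B combination needs data")
        self.df = {
            "a": A - 1,
            "b": B - 1,
            "ab": (A - 1) * (B - 1),
            "error": self.n - A * B,
        }
        if self.df["error"] <= 0:
            raise ValueError("no error degrees of freedom (need replicate trials per cell)")

        one = np.ones((self.n, 1))
        za = (a[:, None] == np.arange(A)).astype(float)
        zb = (b[:, None] == np.arange(B)).astype(float)
        zc = (cell[:, None] == np.arange(A * B)).astype(float)
        # Reduced-QR bases for the nested model sequence; RSS under model M
        # is y'y - ||Q_M' y||^2.
        self._q_a = np.linalg.qr(np.hstack([one, za[:, 1:]]))[0]
        self._q_b = np.linalg.qr(np.hstack([one, zb[:, 1:]]))[0]
        self._q_add = np.linalg.qr(np.hstack([one, za[:, 1:], zb[:, 1:]]))[0]
        self._q_full = np.linalg.qr(zc)[0]

    # ------------------------------------------------------------------
    def sums_of_squares(self, y: np.ndarray) -> dict[str, np.ndarray]:
        """Type-II SS per term for each column of ``y`` (shape ``(n, m)`` or ``(n,)``).

        Returns a dict with keys ``a``, ``b``, ``ab``, ``error``, ``total``;
        each value is an array of length ``m`` (scalar ndarray for 1-D input).
        """
        y = np.asarray(y, dtype=float)
        squeeze = y.ndim == 1
        if squeeze:
            y = y[:, None]
        if y.shape[0] != self.n:
            raise ValueError(f"response has {y.shape[0]} rows, design has {self.n}")
        css = np.einsum("ij,ij->j", y, y)

        def rss(q):
            proj = q.T @ y
            return css - np.einsum("ij,ij->j", proj, proj)

        rss_a, rss_b = rss(self._q_a), rss(self._q_b)
        rss_add, rss_full = rss(self._q_add), rss(self._q_full)
        grand = y.mean(axis=0)
        ss = {
            "a": np.maximum(rss_b - rss_add, 0.0),
            "b": np.maximum(rss_a - rss_add, 0.0),
            "ab": np.maximum(rss_add - rss_full, 0.0),
            "error": np.maximum(rss_full, 0.0),
            "total": np.maximum(css - self.n * grand**2, 0.0),
        }
        if squeeze:
            ss = {k: v[0] for k, v in ss.items()}
        return ss

    def anova(self, y: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
        """F statistics and p-values for the three terms, columnwise."""
        ss = self.sums_of_squares(y)
        ms_error = ss["error"] / self.df["error"]
        out = {}
        for term in ("a", "b", "ab"):
            with np.errstate(divide="ignore", invalid="ignore"):
                f = (ss[term] / self.df[term]) / ms_error
            f = np.where(ms_error > 0, f, np.inf)
            p = stats.f.sf(f, self.df[term], self.df["error"])
            out[term] = {"F": f, "p": p, "ss": ss[term]}
        out["ms_error"] = ms_error
        out["ss_total"] = ss["total"]
        return out

    def omega_squared(self, y: np.ndarray) -> dict[str, np.ndarray]:
        """Small-sample-unbiased percent explained variance per term.

        omega^2 = (SS_term - df_term * MS_error) / (SS_total + MS_error) * 100.
        Values may be slightly negative by construction; they are returned
        as computed.
        """
        ss = self.sums_of_squares(y)
        ms_error = ss["error"] / self.df["error"]
        denom = ss["total"] + ms_error
        out = {}
        for term in ("a", "b", "ab"):
            with np.errstate(divide="ignore", invalid="ignore"):
                w = (ss[term] - self.df[term] * ms_error) / denom * 100.0
            out[term] = np.where(denom > 0, w, 0.0)
        return out
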