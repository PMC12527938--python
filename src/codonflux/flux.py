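"""Steady-state stable-isotope tracing flux calculus.

All quantities assume isotopic pseudo-steady state under a constant
[U-13C] tracer infusion at rate R (nmol min^-1 g^-1):

* circulatory turnover flux of the infused nutrient,
  ``F_circ = R * (1 - L[M+C]) / L[M+C]`` where L[M+C] is the fully
  labeled serum fraction;
* carbon-atom turnover flux ``F_circ_atom = C * R * (1 - L) / L`` with
  ``L = sum_i i * L[M+i] / C`` the labeled-carbon-atom fraction;
* normalized labeling of a downstream metabolite Y under tracer X,
  ``L_{Y<-X} = L_Y / L_X``;
* direct contributions of circulating metabolites to a tissue pool,
  solved as non-negative least squares ``min ||M f - L||, f >= 0``
  where M is the circulating interconversion matrix, with bootstrap
  standard errors from Gaussian resampling of M and L.

The deconvolution is exposed in the fit-and-results style:
``SourceContributionModel(M, L).fit()`` returns a
:class:`ContributionResults` carrying the estimates, bootstrap
standard errors and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from codonflux.types import MIDVector


# ---------------------------------------------------------------------------
# turnover fluxes and labeling fractions
# ---------------------------------------------------------------------------

def fcirc(R: float, mid: MIDVector) -> float:
    """Circulatory turnover flux of the infused nutrient.

    ``F_circ = R * (1 - L[M+C]) / L[M+C]``; units follow R
    (nmol min^-1 g^-1).  A fully labeled serum pool (L[M+C] = 1) means
    zero endogenous turnover.
    """
    if R <= 0:
        raise ValueError("infusion rate R must be > 0")
    lc = mid.fully_labeled
    if lc <= 0:
        raise ValueError(
            f"{mid.metabolite}: fully labeled fraction is 0; turnover undefined"
        )
    return R * (1.0 - lc) / lc


def atom_fraction(mid: MIDVector) -> float:
    """Fraction of labeled carbon atoms: ``L = sum_i i * L[M+i] / C``."""
    fr = np.asarray(mid.fractions, dtype=float)
    C = mid.carbon_count
    return float(np.dot(np.arange(C + 1), fr) / C)


def fcirc_atom(R: float, C: int, L: float) -> float:
    """Carbon-atom circulatory turnover flux: ``C * R * (1 - L) / L``.

    Units nmolC min^-1 g^-1.  Reduces to :func:`fcirc` for C = 1 and a
    binary M+0/M+C distribution.
    """
    if R <= 0:
        raise ValueError("infusion rate R must be > 0")
    if C < 1:
        raise ValueError("carbon count C must be >= 1")
    if not 0 < L <= 1:
        raise ValueError(f"labeled atom fraction L={L} must be in (0, 1]")
    return C * R * (1.0 - L) / L


def normalized_labeling(L_Y: float, L_X: float) -> float:
    """Labeling of downstream metabolite Y normalized to the tracer X.

    ``L_{Y<-X} = L_Y / L_X`` where both are labeled-carbon-atom
    fractions.
    """
    if L_X <= 0:
        raise ValueError("tracer atom fraction L_X must be > 0 (tracer did not enrich)")
    if L_Y < 0:
        raise ValueError("L_Y must be >= 0")
    return L_Y / L_X


def infusion_rate(conc_mM: float, pump_ul_min_g: float) -> float:
    """Tracer infusion rate R in nmol min^-1 g^-1.

    mM x ul min^-1 g^-1 = nmol min^-1 g^-1 (1 mM = 1 nmol/ul).
    """
    if conc_mM <= 0 or pump_ul_min_g <= 0:
        raise ValueError("concentration and pump rate must be > 0")
    return conc_mM * pump_ul_min_g


def validate_interconversion(M: pd.DataFrame) -> pd.DataFrame:
    """Check an interconversion matrix: square, diagonal 1, entries >= 0.

    Rows are infused tracers, columns are labeled metabolites; entry
    (X, Y) is the normalized labeling L_{Y<-X} of Y when X is infused.
    The diagonal (a tracer's own normalized labeling) is 1 by
    definition.
    """
    if M.shape[0] != M.shape[1] or not (M.index == M.columns).all():
        raise ValueError("interconversion matrix must be square with matching labels")
    vals = M.to_numpy(dtype=float)
    if not np.allclose(np.diag(vals), 1.0, atol=1e-9):
        raise ValueError("interconversion matrix diagonal must be 1")
    if np.any(vals < 0):
        raise ValueError("interconversion matrix entries must be >= 0")
    return M


# ---------------------------------------------------------------------------
# direct-contribution deconvolution (model / results)
# ---------------------------------------------------------------------------

class SourceContributionModel:
    """Non-negative deconvolution of a tissue metabolite's direct sources.

    Solves ``min ||M f - L||_2`` subject to ``f >= 0`` where ``M`` is
    the circulating interconversion matrix (targets x tracers) and
    ``L`` the measured normalized labeling of the tissue metabolite
    under each tracer.  Contributions are not forced to sum to 1; the
    slack ``1 - sum(f)`` is reported as the unexplained fraction.

    Parameters
    ----------
    M : array-like or DataFrame, shape (n, n)
        Circulating interconversion matrix.
    L : array-like or Series, length n
        Normalized labeling of the target metabolite per tracer.
    sources : sequence of str, optional
        Source names; inferred from ``M`` when it is a DataFrame.
    target : str, optional
        Name of the target metabolite, used in the summary.
    """

    def __init__(self, M, L, sources=None, target="tissue metabolite"):
        if isinstance(M, pd.DataFrame):
            if sources is None:
                sources = list(M.columns)
            M = M.to_numpy(dtype=float)
        else:
            M = np.asarray(M, dtype=float)
        if isinstance(L, pd.Series):
            L = L.to_numpy(dtype=float)
        else:
            L = np.asarray(L, dtype=float)
        if M.ndim != 2:
            raise ValueError("M must be a matrix")
        if L.shape != (M.shape[0],):
            raise ValueError(
                f"dimension mismatch: M is {M.shape}, L has length {L.shape}"
            )
        if sources is None:
            sources = [f"source{i}" for i in range(M.shape[1])]
        if len(sources) != M.shape[1]:
            raise ValueError("sources length must match M columns")
        self.M = M
        self.L = L
        self.sources = list(sources)
        self.target = target

    def fit(
        self,
        M_sd=None,
        L_sd=None,
        n_boot: int = 100,
        seed: int | None = None,
        clip_negative: bool = True,
    ) -> "ContributionResults":
        """Solve the NNLS problem, optionally with bootstrap errors.

        When measurement standard deviations ``M_sd`` and ``L_sd`` are
        given, ``n_boot`` simulations redraw every entry of M and L from
        ``Normal(mean, sd)`` (clipped at 0 unless ``clip_negative`` is
        False) and re-solve; the bootstrap SE of each contribution is
        the standard deviation of its estimates across simulations.
        """
        f, rnorm = nnls(self.M, self.L)
        bse = None
        boot = None
        if M_sd is not None or L_sd is not None:
            M_sd = np.zeros_like(self.M) if M_sd is None else np.broadcast_to(
                np.asarray(M_sd, dtype=float), self.M.shape
            )
            L_sd = np.zeros_like(self.L) if L_sd is None else np.broadcast_to(
                np.asarray(L_sd, dtype=float), self.L.shape
            )
            if np.any(M_sd < 0) or np.any(L_sd < 0):
                raise ValueError("standard deviations must be >= 0")
            rng = np.random.default_rng(seed)
            draws = np.empty((n_boot, len(self.sources)))
            for b in range(n_boot):
                Mb = rng.normal(self.M, M_sd)
                Lb = rng.normal(self.L, L_sd)
                if clip_negative:
                    Mb = np.clip(Mb, 0.0, None)
                    Lb = np.clip(Lb, 0.0, None)
                draws[b], _ = nnls(Mb, Lb)
            bse = draws.std(axis=0, ddof=1)
            boot = draws
        return ContributionResults(self, f, rnorm, bse=bse, boot_draws=boot)


@dataclass
class ContributionResults:
    """Fitted direct-contribution fractions of one tissue metabolite."""

    model: SourceContributionModel
    _params: np.ndarray
    resid_norm: float
    bse: np.ndarray | None = None
    boot_draws: np.ndarray | None = None

    @property
    def params(self) -> pd.Series:
        """Estimated non-negative contribution fractions per source."""
        return pd.Series(self._params, index=self.model.sources, name="f")

    @property
    def unexplained(self) -> float:
        """Slack 1 - sum(f): fraction not attributed to any source."""
        return float(1.0 - self._params.sum())

    def summary(self) -> str:
        lines = [
            f"Direct contributions to {self.model.target}",
            f"  n sources: {len(self.model.sources)}   "
            f"residual norm: {self.resid_norm:.6g}   "
            f"unexplained: {self.unexplained:.4f}",
            f"  {'source':<20}{'f':>10}{'boot SE':>12}",
        ]
        for i, s in enumerate(self.model.sources):
            se = f"{self.bse[i]:.4f}" if self.bse is not None else "-"
            lines.append(f"  {s:<20}{self._params[i]:>10.4f}{se:>12}")
        return "\n".join(lines)


def direct_contributions(M, L, **kwargs) -> ContributionResults:
    """Functional shorthand for ``SourceContributionModel(M, L).fit()``."""
    target = kwargs.pop("target", "tissue metabolite")
    sources = kwargs.pop("sources", None)
    return SourceContributionModel(M, L, sources=sources, target=target).fit(**kwargs)


# ---------------------------------------------------------------------------
# circulating flux network
# ---------------------------------------------------------------------------

def flux_network(
    M: pd.DataFrame, fcirc_atoms: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Direct inter-nutrient fluxes among circulating metabolites.

    For each circulating nutrient i the direct contributions from the
    other nutrients are solved by NNLS on the interconversion matrix
    restricted to tracers and sources j != i: each equation row is a
    tracer X with ``sum_j L_{j<-X} f_{i<-j} = L_{i<-X}``.  The result
    is the matrix N (rows: targets, columns: sources; N_ij = direct
    contribution of j to i); the edge flux from j to i is
    ``N_ij * F_circ_atom(i)``, in nmolC min^-1 g^-1.

    Returns ``(N, edges)`` where edges is a (source, target, flux)
    table with self-edges excluded.
    """
    validate_interconversion(M)
    mets = list(M.index)
    missing = [m for m in mets if m not in fcirc_atoms.index]
    if missing:
        raise ValueError(f"missing F_circ_atom for metabolites: {missing}")
    N = pd.DataFrame(0.0, index=mets, columns=mets)
    for target in mets:
        sources = [m for m in mets if m != target]
        if not sources:
            continue
        sub = M.loc[sources, sources]
        L = M.loc[sources, target]
        res = SourceContributionModel(
            sub, L, sources=sources, target=target
        ).fit()
        N.loc[target, sources] = res.params.values
    rows = []
    for target in mets:
        for source in mets:
            if source == target:
                continue
            flux = N.loc[target, source] * float(fcirc_atoms[target])
            rows.append({"source": source, "target": target, "flux": flux})
    return N, pd.DataFrame(rows)
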