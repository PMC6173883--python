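"""Galaxy biplots: allelic associations for one environment against another.

Each SNP is a point (rho(f, E1), rho(f, E2)). Because alleles are coded
relative to the ancestral state, a point shows the bivariate environment in
which the derived allele is at elevated frequency; recoding an allele
reflects its point through the origin. The genome-wide null backdrop is a
(1 - alpha) prediction ellipse of the bivariate normal fitted to all SNPs:
semi-axis lengths l_j = sqrt(lambda_j * q) with lambda_j the eigenvalues of
the 2x2 sample covariance and q the chi-square(df=2) quantile at
probability 1 - alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .associations import AssociationMatrix
from .data_io import EnvMatrix

__all__ = [
    "Ellipse",
    "biplot_coordinates",
    "prediction_ellipse",
    "ellipse_coverage",
    "plot_galaxy",
]

MANY_SNPS_WARN = 200  # below this, the genome-wide-null assumption is shaky


@dataclass
class Ellipse:
    """An alpha-level bivariate prediction ellipse."""

    center: np.ndarray       # (2,)
    semi_axes: np.ndarray    # (l1, l2) with l1 >= l2 > 0
    orientation: float       # radians of the major axis, in (-pi/2, pi/2]
    alpha: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.semi_axes = np.asarray(self.semi_axes, dtype=float)
        l1, l2 = self.semi_axes
        if not (l1 >= l2 > 0):
            raise ValueError("semi-axes must satisfy l1 >= l2 > 0")
        if not (-np.pi / 2 < self.orientation <= np.pi / 2):
            raise ValueError("orientation must lie in (-pi/2, pi/2]")

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])

    def covariance(self) -> np.ndarray:
        """Back out the 2x2 covariance the ellipse was fitted from."""
        q = stats.chi2.ppf(1 - self.alpha, df=2)
        lam = self.semi_axes ** 2 / q
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        R = np.array([[c, -s], [s, c]])
        return R @ np.diag(lam) @ R.T

    def boundary(self, n: int = 200) -> np.ndarray:
        """n points on the ellipse boundary (for plotting)."""
        t = np.linspace(0, 2 * np.pi, n)
        xy = np.stack([self.semi_axes[0] * np.cos(t),
                       self.semi_axes[1] * np.sin(t)])
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        R = np.array([[c, -s], [s, c]])
        return (R @ xy).T + self.center


def biplot_coordinates(assoc: AssociationMatrix, env1: str, env2: str,
                       derived_only: bool = True,
                       derived_known: pd.Series | None = None,
                       envs: EnvMatrix | None = None) -> pd.DataFrame:
    """Per-SNP biplot points (rho with env1, rho with env2).

    With ``derived_only`` SNPs whose ancestral state is unknown are dropped
    (their position would depend on an arbitrary reference polarity). If
    ``envs`` is given, the Spearman correlation between the two variables is
    attached as ``.attrs['env_corr']`` for quadrant shading: with a positive
    environment-environment correlation, genome-wide covariance of allelic
    effects is expected in quadrants 1 and 3.
    """
    if env1 == env2:
        raise ValueError("env1 and env2 must differ")
    for e in (env1, env2):
        if e not in assoc.environments:
            raise KeyError(f"unknown environment: {e}")
    pts = assoc.rho[[env1, env2]].copy()
    pts.columns = ["x", "y"]
    if derived_only and derived_known is not None:
        keep = derived_known.reindex(pts.index).fillna(False).astype(bool)
        pts = pts.loc[keep]
    pts = pts.dropna()
    if envs is not None:
        corr, _ = stats.spearmanr(envs.values[env1], envs.values[env2])
        pts.attrs["env_corr"] = float(corr)
        pts.attrs["shaded_quadrants"] = (1, 3) if corr >= 0 else (2, 4)
    pts.attrs["env1"], pts.attrs["env2"] = env1, env2
    return pts


def prediction_ellipse(points, alpha: float = 0.05) -> Ellipse:
    """Fit the (1 - alpha) prediction ellipse of a 2-D sample.

    Center = sample means; axes from the eigendecomposition of the sample
    (n-1 denominator) covariance, scaled by the square root of the
    chi-square(df=2) quantile at probability 1 - alpha.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        X = X.reshape(-1, 2)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need >= 3 points")
    if n < MANY_SNPS_WARN:
        warnings.warn(
            f"only {n} SNPs: the genome-wide-null ellipse assumes a large "
            "number of unlinked SNPs", stacklevel=2)
    cov = np.cov(X, rowvar=False, ddof=1)
    lam, vec = np.linalg.eigh(cov)          # ascending
    if lam[0] <= 1e-12 * max(lam[1], 1e-300):
        raise ValueError("points are (near-)collinear: singular covariance")
    q = stats.chi2.ppf(1 - alpha, df=2)
    order = [1, 0]
    lam, vec = lam[order], vec[:, order]
    angle = np.arctan2(vec[1, 0], vec[0, 0])
    if angle <= -np.pi / 2:
        angle += np.pi
    elif angle > np.pi / 2:
        angle -= np.pi
    return Ellipse(X.mean(axis=0), np.sqrt(lam * q), float(angle), alpha)


def ellipse_coverage(points, ellipse: Ellipse) -> float:
    """Fraction of points inside the ellipse (quadratic form <= chi-square
    quantile). For multivariate-normal data this approaches 1 - alpha."""
    X = np.asarray(points, dtype=float).reshape(-1, 2)
    cov = ellipse.covariance()
    q = stats.chi2.ppf(1 - ellipse.alpha, df=2)
    d = X - ellipse.center
    sol = np.linalg.solve(cov, d.T)
    m = np.einsum("ij,ji->i", d, sol)
    return float(np.mean(m <= q))


def plot_galaxy(points: pd.DataFrame, ellipse: Ellipse, ax=None,
                module_of_snp: dict | None = None):
    """Render a galaxy biplot: points, prediction ellipse, quadrant shading."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    quads = points.attrs.get("shaded_quadrants")
    if quads is not None:
        lim = 1.05 * float(np.abs(points[["x", "y"]].to_numpy()).max())
        for qd in quads:
            sx = 1 if qd in (1, 4) else -1
            sy = 1 if qd in (1, 2) else -1
            ax.fill([0, sx * lim, sx * lim, 0], [0, 0, sy * lim, sy * lim],
                    color="0.9", zorder=0)
    if module_of_snp:
        colors = pd.Series({s: module_of_snp.get(s) for s in points.index})
        for mod, grp in points.groupby(colors):
            ax.scatter(grp["x"], grp["y"], s=6, label=str(mod))
        ax.legend(fontsize=6, title="module")
    else:
        ax.scatter(points["x"], points["y"], s=5, color="0.4")
    b = ellipse.boundary()
    ax.plot(b[:, 0], b[:, 1], "k-", lw=1)
    ax.axhline(0, color="0.7", lw=0.5)
    ax.axvline(0, color="0.7", lw=0.5)
    ax.set_xlabel(f"rho with {points.attrs.get('env1', 'E1')}")
    ax.set_ylabel(f"rho with {points.attrs.get('env2', 'E2')}")
    return ax
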