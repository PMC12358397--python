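"""Synthetic landscapes with known truth for end-to-end testing.

The generator emulates the structure of a real gridded study system:
co-registered, spatially autocorrelated continuous predictors; a virtual
host species with a known logistic (linear + quadratic) environmental
response; a virtual obligate parasite whose true suitability is the
product of its own environmental response and an indicator that host truth
exceeds a parasitism threshold; and presence points sampled from truth.
Because the truth is known, every pipeline stage — thinning, selection,
fitting, the host constraint, classification, change and overlay — can be
checked without any external data download.

Random fields are built by Gaussian-kernel smoothing of white noise, with
inter-layer correlation induced by mixing each layer with a shared latent
field; both knobs (correlation length in cells, target pairwise r) are
statistically controllable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .grid_io import GridLayer
from .occurrences import OccurrenceSet

__all__ = [
    "VirtualSpecies",
    "default_template",
    "generate_env_layers",
    "make_virtual_species",
    "make_parasite",
    "sample_occurrences",
    "make_study_system",
    "HOST_RESPONSE",
    "PARASITE_RESPONSE",
]

# Canonical virtual study system: a widespread host shrub and a narrow-niche
# obligate parasite.  With near-uniform predictor marginals these responses
# put ~35-40% of the landscape above the host parasitism threshold and
# ~10-15% above the parasite suitability threshold — the suitable fraction a
# desert specialist of this kind occupies in its study window.
HOST_RESPONSE = {"vars": {"env1": (60.0, -30.0), "env2": (16.0, 0.0)}, "intercept": -34.0}
PARASITE_RESPONSE = {"vars": {"env2": (44.0, -12.0), "env3": (20.0, 0.0)}, "intercept": -42.0}


@dataclass
class VirtualSpecies:
    """A species with known truth on the grid.

    ``response`` maps variable name -> (linear, quadratic) coefficients of
    the logit of the truth; ``host_mask_threshold`` is set on parasites and
    records the host-truth cutoff baked into ``truth_layer``.
    """

    name: str
    response: dict[str, tuple[float, float]]
    intercept: float
    truth_layer: GridLayer
    host_mask_threshold: float | None = None

    def __post_init__(self) -> None:
        v = self.truth_layer.values
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("truth must lie in [0, 1]")


def default_template(nrows: int = 100, ncols: int = 100, xll: float = 80.0,
                     yll: float = 35.0, cellsize: float = 2.5 / 60.0) -> GridLayer:
    """An all-zero template grid; defaults give a 2.5 arc-minute grid placed
    in mid-latitudes (comparable to an arid-belt study window)."""
    return GridLayer(nrows, ncols, xll, yll, cellsize,
                     values=np.zeros((nrows, ncols)), kind="continuous")


def _smooth_unit_field(shape, smoothness, rng) -> np.ndarray:
    z = rng.standard_normal(shape)
    if smoothness > 0:
        z = gaussian_filter(z, sigma=smoothness, mode="reflect")
    return z


def generate_env_layers(
    template: GridLayer,
    n_layers: int,
    smoothness: float = 5.0,
    pairwise_r: float = 0.0,
    seed: int | None = None,
) -> list[GridLayer]:
    """Spatially autocorrelated predictor layers rescaled to [0, 1].

    ``smoothness`` is the Gaussian kernel width in cells (0 = white noise);
    ``pairwise_r`` the target correlation between any two layers, induced
    by mixing a shared latent field (negative targets are only possible
    for exactly two layers).
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if not (-1.0 < pairwise_r < 1.0):
        raise ValueError("|pairwise_r| must be < 1")
    if pairwise_r < 0 and n_layers > 2:
        raise ValueError("a common negative pairwise correlation is only "
                         "achievable for 2 layers")
    rng = np.random.default_rng(seed)
    shape = template.shape
    shared = _smooth_unit_field(shape, smoothness, rng)
    w = np.sqrt(abs(pairwise_r))
    layers = []
    for i in range(n_layers):
        own = _smooth_unit_field(shape, smoothness, rng)
        sign = -1.0 if (pairwise_r < 0 and i == 1) else 1.0
        f = sign * w * shared + np.sqrt(1 - w ** 2) * own
        # standardize, then map through the normal CDF: every layer gets a
        # stable near-uniform [0,1] marginal regardless of seed or kernel
        sd = f.std()
        z = (f - f.mean()) / (sd if sd > 0 else 1.0)
        vals = norm.cdf(z)
        layers.append(template.copy_with(vals, kind="continuous", name=f"env{i + 1}"))
    return layers


def make_virtual_species(
    env_layers: list[GridLayer],
    coefficients: dict[str, tuple[float, float]],
    intercept: float = 0.0,
    name: str = "virtual_species",
) -> VirtualSpecies:
    """Truth = inverse-logit of a linear+quadratic predictor over the layers."""
    by_name = {lyr.name: lyr for lyr in env_layers}
    missing = set(coefficients) - set(by_name)
    if missing:
        raise ValueError(f"coefficients reference unknown layers: {sorted(missing)}")
    eta = np.full(env_layers[0].shape, float(intercept))
    for var, (b1, b2) in coefficients.items():
        z = by_name[var].values
        eta = eta + b1 * z + b2 * z ** 2
    truth = 1.0 / (1.0 + np.exp(-eta))
    nodata = ~np.all([np.isfinite(l.values) for l in env_layers], axis=0)
    truth[nodata] = np.nan
    layer = env_layers[0].copy_with(truth, kind="continuous", name=f"{name}_truth")
    return VirtualSpecies(name=name, response=dict(coefficients),
                          intercept=intercept, truth_layer=layer)


def make_parasite(
    host: VirtualSpecies,
    env_layers: list[GridLayer],
    coefficients: dict[str, tuple[float, float]],
    intercept: float = 0.0,
    theta_true: float = 0.4,
    name: str = "virtual_parasite",
) -> VirtualSpecies:
    """Parasite truth = own environmental response x 1[host truth >= theta]."""
    env_sp = make_virtual_species(env_layers, coefficients, intercept, name=name)
    mask = host.truth_layer.values >= theta_true
    truth = np.where(mask, env_sp.truth_layer.values, 0.0)
    truth[~np.isfinite(host.truth_layer.values)] = np.nan
    layer = env_layers[0].copy_with(truth, kind="continuous", name=f"{name}_truth")
    return VirtualSpecies(name=name, response=dict(coefficients),
                          intercept=intercept, truth_layer=layer,
                          host_mask_threshold=theta_true)


def make_study_system(
    template: GridLayer | None = None,
    seed: int | None = None,
    n_layers: int = 3,
    smoothness: float = 8.0,
    pairwise_r: float = 0.3,
    theta_true: float = 0.4,
) -> tuple[list[GridLayer], VirtualSpecies, VirtualSpecies]:
    """The canonical synthetic host-parasite system: (env, host, parasite).

    Three moderately correlated predictors; host and parasite responses are
    the module defaults above.  Everything downstream (thinning, tuning,
    the two scenarios, classification, overlay) can run on the output.
    """
    if template is None:
        template = default_template()
    env = generate_env_layers(template, n_layers, smoothness, pairwise_r, seed)
    host = make_virtual_species(env, HOST_RESPONSE["vars"],
                                HOST_RESPONSE["intercept"], name="virtual_host")
    parasite = make_parasite(host, env, PARASITE_RESPONSE["vars"],
                             PARASITE_RESPONSE["intercept"], theta_true,
                             name="virtual_parasite")
    return env, host, parasite


def sample_occurrences(species: VirtualSpecies, n: int, seed: int | None = None) -> OccurrenceSet:
    """Sample n presence cells without replacement, probability ∝ truth;
    occurrence points sit at cell centers."""
    truth = species.truth_layer
    v = truth.values
    ok = np.isfinite(v) & (v > 0)
    if not ok.any():
        raise ValueError("truth has no positive mass")
    rows, cols = np.nonzero(ok)
    weights = v[rows, cols]
    weights = weights / weights.sum()
    if n > rows.size:
        raise ValueError(f"cannot draw {n} cells from {rows.size} with positive truth")
    rng = np.random.default_rng(seed)
    pick = rng.choice(rows.size, size=n, replace=False, p=weights)
    records = []
    for idx in pick:
        lon, lat = truth.cell_center(int(rows[idx]), int(cols[idx]))
        records.append((lon, lat, "synthetic"))
    return OccurrenceSet(species=species.name, records=records)
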