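"""Fixed Gaussian-basis encoding of grid positions.

A one-hot 20x20 position input is projected through a fixed connection
table ``M`` onto 900 hidden units.  Each hidden unit k has a Gaussian
receptive field centred on a grid square ``(a_k, b_k)``, with centres
spread linearly over the grid and a per-unit variance drawn from a
log-normal distribution controlled by the generalization metaparameter
theta.  Optionally, sparse additive noise (value ``A`` with probability
``rho``, independently per connection) is frozen into ``M`` to emulate a
disturbed encoding.  The table is fixed: only downstream readout weights
are ever learned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class BasisSpec:
    """Parameters of the fixed encoder.

    theta > 0 scales the log-normal width distribution
    ``sigma_k^2 ~ LogN(-0.7/theta, 0.7*theta)`` (location, SD of the log by
    default; set ``log_scale_is_sd=False`` to read the second argument as
    the variance of the log instead).
    """

    theta: float = 1.0
    n_hidden: int = 900
    width: int = 20
    height: int = 20
    noise_strength: float = 0.0  # A
    noise_fraction: float = 0.0  # rho
    seed: int = 0
    log_scale_is_sd: bool = True

    @property
    def n_input(self) -> int:
        return self.width * self.height

    def validate(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.noise_strength < 0:
            raise ValueError("noise strength A must be >= 0")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise fraction rho must lie in [0, 1]")


def encode_position(x: int, y: int, width: int = 20, height: int = 20) -> np.ndarray:
    """One-hot indicator I(x, y): 1 at (x, y), 0 elsewhere."""
    if not (1 <= x <= width and 1 <= y <= height):
        raise ValueError(f"position ({x}, {y}) outside 1..{width} x 1..{height}")
    out = np.zeros((width, height))
    out[x - 1, y - 1] = 1.0
    return out


def build_centers(n_hidden: int = 900, n_input: int = 400, width: int = 20):
    """Receptive-field centres: unit k sits at the grid square with linear
    index ceil(n_input * k / n_hidden), so 900 centres spread evenly over
    the 400 squares (2-3 units per square)."""
    k = np.arange(1, n_hidden + 1, dtype=np.int64)
    lin = (n_input * k + n_hidden - 1) // n_hidden  # integer ceil
    a = (lin - 1) // width + 1
    b = (lin - 1) % width + 1
    return a.astype(np.intp), b.astype(np.intp)


def sample_variances(
    theta: float,
    n_hidden: int,
    rng: np.random.Generator,
    *,
    log_scale_is_sd: bool = True,
) -> np.ndarray:
    """Per-unit Gaussian variances sigma_k^2 ~ LogN(-0.7/theta, 0.7*theta)."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    scale = 0.7 * theta
    sigma_log = scale if log_scale_is_sd else float(np.sqrt(scale))
    return rng.lognormal(mean=-0.7 / theta, sigma=sigma_log, size=n_hidden)


def sample_noise(
    strength: float,
    fraction: float,
    n_input: int,
    n_hidden: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sparse frozen connection noise: each entry equals ``strength`` with
    probability ``fraction``, else 0; drawn once, never relearned."""
    if strength < 0:
        raise ValueError("noise strength A must be >= 0")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("noise fraction rho must lie in [0, 1]")
    return strength * (rng.random((n_input, n_hidden)) < fraction)


@dataclass(frozen=True)
class BasisNetwork:
    """The frozen connection table plus its provenance.

    ``M`` has shape (width, height, n_hidden); ``M[x-1, y-1, k]`` is the
    response of hidden unit k to position (x, y), i.e. the hidden activity
    is a plain row extraction of the one-hot matrix product.
    """

    M: np.ndarray
    centers: tuple[np.ndarray, np.ndarray]
    variances: np.ndarray
    spec: BasisSpec

    @property
    def M_flat(self) -> np.ndarray:
        """(n_input, n_hidden) view with input index 20*(i-1) + (j-1)."""
        return self.M.reshape(self.spec.n_input, self.spec.n_hidden)

    def hidden_activity(self, x: int, y: int) -> np.ndarray:
        if not (1 <= x <= self.spec.width and 1 <= y <= self.spec.height):
            raise ValueError(f"position ({x}, {y}) outside the grid")
        return self.M[x - 1, y - 1]


def build_basis(spec: BasisSpec) -> BasisNetwork:
    """Construct the fixed table M = (Gaussian(center, sigma^2) + noise)/D.

    Named substreams: variances come from the first child of the seed and
    connection noise from the second, so varying the noise setting never
    perturbs the width draws.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    var_stream, noise_stream = ss.spawn(2)
    variances = sample_variances(
        spec.theta,
        spec.n_hidden,
        np.random.default_rng(var_stream),
        log_scale_is_sd=spec.log_scale_is_sd,
    )
    a, b = build_centers(spec.n_hidden, spec.n_input, spec.width)
    i = np.arange(1, spec.width + 1)[:, None, None]
    j = np.arange(1, spec.height + 1)[None, :, None]
    dist2 = (i - a[None, None, :]) ** 2 + (j - b[None, None, :]) ** 2
    table = np.exp(-dist2 / (2.0 * variances[None, None, :]))
    if spec.noise_strength > 0 and spec.noise_fraction > 0:
        eps = sample_noise(
            spec.noise_strength,
            spec.noise_fraction,
            spec.n_input,
            spec.n_hidden,
            np.random.default_rng(noise_stream),
        )
        table = table + eps.reshape(spec.width, spec.height, spec.n_hidden)
    table /= spec.n_input
    return BasisNetwork(M=table, centers=(a, b), variances=variances, spec=spec)


# ---------------------------------------------------------------------------
# Plain-text export for reproducibility audits
# ---------------------------------------------------------------------------


def save_basis(net: BasisNetwork, prefix: str | Path) -> None:
    """Write M as a TSV table (rows = input index, column-major over hidden
    units) plus a JSON sidecar holding the spec, centres and variances."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".tsv"), net.M_flat, delimiter="\t")
    sidecar = {
        "spec": {
            "theta": net.spec.theta,
            "n_hidden": net.spec.n_hidden,
            "width": net.spec.width,
            "height": net.spec.height,
            "noise_strength": net.spec.noise_strength,
            "noise_fraction": net.spec.noise_fraction,
            "seed": net.spec.seed,
            "log_scale_is_sd": net.spec.log_scale_is_sd,
        },
        "centers_a": net.centers[0].tolist(),
        "centers_b": net.centers[1].tolist(),
        "variances": net.variances.tolist(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def load_basis(prefix: str | Path) -> BasisNetwork:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    spec = BasisSpec(**sidecar["spec"])
    m_flat = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t")
    return BasisNetwork(
        M=m_flat.reshape(spec.width, spec.height, spec.n_hidden),
        centers=(np.array(sidecar["centers_a"]), np.array(sidecar["centers_b"])),
        variances=np.array(sidecar["variances"]),
        spec=spec,
    )
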