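"""Binary-binary Restricted Boltzmann Machine.

The RBM is trained as a density model of flattened contact maps; the
energy of a joint configuration is

    E(v, h) = -b·v - c·h - v·W·h

with visible units v (one per nucleotide pair of the template map),
hidden units h, connection weights W and biases b, c.  Training uses
contrastive divergence (CD-k, full batch by default); the structural
contact-frequency template is the per-unit mean of Gibbs samples drawn
from the trained machine.

Small machines (≤ 24 total units) additionally support exact
enumeration — partition function, marginals, likelihood and gradients —
which serve as independent oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .contact_maps import TEMPLATE_SIZE, unflatten_values

ENUM_LIMIT = 24


@dataclass
class RBMModel:
    """Parameters of a binary-binary RBM.

    ``weight`` has shape (n_visible, n_hidden); ``visible_bias`` (b) and
    ``hidden_bias`` (c) match.  ``config`` records how the model was
    trained so a saved model can be reproduced.
    """

    weight: np.ndarray
    visible_bias: np.ndarray
    hidden_bias: np.ndarray
    rng_seed: int = 0
    config: dict = field(default_factory=dict)

    @property
    def n_visible(self) -> int:
        return self.weight.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.weight.shape[1]

    def _check(self) -> None:
        if self.visible_bias.shape != (self.n_visible,) or self.hidden_bias.shape != (
            self.n_hidden,
        ):
            raise ValueError("dimension error")


@dataclass
class SampleSet:
    """Visible-layer samples kept from a Gibbs chain."""

    samples: np.ndarray  # (n_kept, n_visible) uint8
    n_total_steps: int
    n_kept: int


def zero_model(n_visible: int, n_hidden: int) -> RBMModel:
    return RBMModel(
        np.zeros((n_visible, n_hidden)), np.zeros(n_visible), np.zeros(n_hidden)
    )


def energy(m: RBMModel, v: np.ndarray, h: np.ndarray) -> float:
    """E(v, h) = -b·v - c·h - v·W·h."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (m.n_visible,) or h.shape != (m.n_hidden,):
        raise ValueError("dimension error")
    return float(-m.visible_bias @ v - m.hidden_bias @ h - v @ m.weight @ h)


def conditional_hidden(m: RBMModel, v: np.ndarray) -> np.ndarray:
    """P(h_j = 1 | v) = logistic(c_j + Σ_i W_ij v_i); accepts a batch."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != m.n_visible:
        raise ValueError("dimension error")
    return expit(m.hidden_bias + v @ m.weight)


def conditional_visible(m: RBMModel, h: np.ndarray) -> np.ndarray:
    """P(v_i = 1 | h) = logistic(b_i + Σ_j W_ij h_j); accepts a batch."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != m.n_hidden:
        raise ValueError("dimension error")
    return expit(m.visible_bias + h @ m.weight.T)


def _all_states(n: int) -> np.ndarray:
    """All 2^n binary vectors of length n, lexicographic."""
    return ((np.arange(2**n)[:, None] >> np.arange(n - 1, -1, -1)) & 1).astype(float)


def _free_energy(m: RBMModel, v: np.ndarray) -> np.ndarray:
    """-log Σ_h exp(-E(v, h)), hidden layer marginalized analytically."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    act = m.hidden_bias + v @ m.weight
    return -(v @ m.visible_bias) - np.logaddexp(0.0, act).sum(axis=1)


def _guard_enumeration(m: RBMModel) -> None:
    if m.n_visible + m.n_hidden > ENUM_LIMIT:
        raise ValueError("enumeration refused: machine too large")


def exact_partition(m: RBMModel) -> float:
    """z = Σ_{v,h} exp(-E); enumeration-guarded test oracle."""
    _guard_enumeration(m)
    fe = _free_energy(m, _all_states(m.n_visible))
    mx = fe.min()
    return float(np.exp(-mx) * np.exp(-(fe - mx)).sum())


def exact_visible_distribution(m: RBMModel) -> np.ndarray:
    """P(v) over all 2^n_visible states, lexicographic order."""
    _guard_enumeration(m)
    fe = _free_energy(m, _all_states(m.n_visible))
    w = np.exp(-(fe - fe.min()))
    return w / w.sum()


def exact_visible_marginals(m: RBMModel) -> np.ndarray:
    """Σ_v v_i P(v) for each visible unit."""
    p = exact_visible_distribution(m)
    return p @ _all_states(m.n_visible)


def negative_log_likelihood(m: RBMModel, data: np.ndarray) -> float:
    """-(1/N) Σ log P(v) by exact enumeration (small machines only)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise ValueError("no samples")
    _guard_enumeration(m)
    fe_all = _free_energy(m, _all_states(m.n_visible))
    mx = fe_all.min()
    log_z = -mx + np.log(np.exp(-(fe_all - mx)).sum())
    return float(np.mean(_free_energy(m, data)) + log_z)


def exact_gradient(m: RBMModel, data: np.ndarray):
    """Exact gradient of the mean negative log-likelihood.

    Returns (gW, gb, gc) with the sign convention of gradient *descent*
    steps ``param -= lr * g``: g = model expectation − data expectation.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    _guard_enumeration(m)
    states = _all_states(m.n_visible)
    p = exact_visible_distribution(m)
    ph_states = conditional_hidden(m, states)
    ph_data = conditional_hidden(m, data)
    model_W = states.T @ (p[:, None] * ph_states)
    model_b = p @ states
    model_c = p @ ph_states
    data_W = data.T @ ph_data / data.shape[0]
    data_b = data.mean(axis=0)
    data_c = ph_data.mean(axis=0)
    return model_W - data_W, model_b - data_b, model_c - data_c


def _bernoulli(rng: np.random.Generator, p: np.ndarray) -> np.ndarray:
    return (rng.random(p.shape) < p).astype(p.dtype)


def cd_gradient(m: RBMModel, data: np.ndarray, rng: np.random.Generator, k: int = 1):
    """One stochastic CD-k gradient estimate (same sign convention as
    :func:`exact_gradient`).

    Positive phase uses the data and hidden probabilities; the negative
    phase runs k Gibbs steps from the data with binary sampled states.
    """
    v0 = np.atleast_2d(np.asarray(data, dtype=float))
    n = v0.shape[0]
    ph0 = conditional_hidden(m, v0)
    h = _bernoulli(rng, ph0)
    for _ in range(k):
        v = _bernoulli(rng, conditional_visible(m, h))
        ph = conditional_hidden(m, v)
        h = _bernoulli(rng, ph)
    gW = (v.T @ h - v0.T @ ph0) / n
    gb = v.mean(axis=0) - v0.mean(axis=0)
    gc = h.mean(axis=0) - ph0.mean(axis=0)
    return gW, gb, gc


def train_cd(
    data,
    n_hidden: int = 100,
    learning_rate: float = 0.1,
    epochs: int = 10_000,
    cd_k: int = 1,
    batch_size: int | None = None,
    seed: int = 0,
    init_scale: float = 0.01,
    log_every: int = 100,
) -> RBMModel:
    """Train an RBM on binary vectors by contrastive divergence.

    Full-batch updates by default (training families are small); weights
    start from a centered Gaussian of scale ``init_scale``, biases at
    zero.  Deterministic given ``seed``.  A reconstruction-error trace is
    kept in ``model.config['history']``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise ValueError("no training data")
    if not np.isin(data, (0.0, 1.0)).all():
        raise ValueError("invalid contact vector: entries must be 0/1")
    n, n_visible = data.shape
    rng = np.random.Generator(np.random.PCG64(seed))
    m = RBMModel(
        weight=rng.normal(0.0, init_scale, size=(n_visible, n_hidden)),
        visible_bias=np.zeros(n_visible),
        hidden_bias=np.zeros(n_hidden),
        rng_seed=seed,
        config={
            "n_hidden": n_hidden,
            "learning_rate": learning_rate,
            "epochs": epochs,
            "cd_k": cd_k,
            "batch_size": batch_size,
            "init_scale": init_scale,
            "seed": seed,
        },
    )
    bs = n if batch_size is None else min(batch_size, n)
    history = []
    for epoch in range(epochs):
        if bs == n:
            batches = [data]
        else:
            order = rng.permutation(n)
            batches = [data[order[s : s + bs]] for s in range(0, n, bs)]
        for batch in batches:
            gW, gb, gc = cd_gradient(m, batch, rng, k=cd_k)
            m.weight -= learning_rate * gW
            m.visible_bias -= learning_rate * gb
            m.hidden_bias -= learning_rate * gc
        if log_every and (epoch % log_every == 0 or epoch == epochs - 1):
            recon = conditional_visible(m, conditional_hidden(m, data))
            history.append((epoch, float(np.mean((recon - data) ** 2))))
    m.config["history"] = history
    return m


def gibbs_sample(
    m: RBMModel,
    n_total: int = 10_000,
    n_keep: int = 5_000,
    seed: int = 0,
    init="random",
) -> SampleSet:
    """Alternating Gibbs chain h|v, v|h; keeps the last ``n_keep`` visible
    samples after burn-in.  Deterministic given ``seed``."""
    if n_keep > n_total:
        raise ValueError("n_keep must not exceed n_total")
    rng = np.random.Generator(np.random.PCG64(seed))
    if isinstance(init, str) and init == "random":
        v = (rng.random(m.n_visible) < 0.5).astype(float)
    else:
        v = np.asarray(init, dtype=float)
        if v.shape != (m.n_visible,):
            raise ValueError("dimension error")
    kept = np.empty((n_keep, m.n_visible), dtype=np.uint8)
    burn = n_total - n_keep
    for t in range(n_total):
        h = _bernoulli(rng, conditional_hidden(m, v))
        v = _bernoulli(rng, conditional_visible(m, h))
        if t >= burn:
            kept[t - burn] = v
    return SampleSet(kept, n_total_steps=n_total, n_kept=n_keep)


@dataclass
class TemplateWeight:
    """Structural contact-frequency template W.

    Per-pair contact frequency over RBM-generated samples, arranged as a
    symmetric template_size × template_size matrix with entries in [0, 1]
    and zero diagonal (self-contacts undefined).
    """

    values: np.ndarray
    template_size: int = TEMPLATE_SIZE
    provenance: dict = field(default_factory=dict)


def contact_weight(s: SampleSet, template_size: int = TEMPLATE_SIZE) -> TemplateWeight:
    """Mean of kept samples, unflattened into a symmetric template."""
    if s.samples.size == 0:
        raise ValueError("no samples")
    freq = s.samples.mean(axis=0)
    values = unflatten_values(freq, template_size)
    np.fill_diagonal(values, 0.0)
    return TemplateWeight(
        values,
        template_size=template_size,
        provenance={"n_total_steps": s.n_total_steps, "n_kept": s.n_kept},
    )
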