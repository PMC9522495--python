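"""Backpropagation network with genetic-algorithm weight initialisation.

A three-layer feedforward network (sigmoid or tanh hidden layer, linear
output) is trained by full-batch gradient descent on mean squared error.
Because gradient descent from a random start is sensitive to the initial
weights, a real-coded genetic algorithm first searches the weight space:
every candidate chromosome is the flattened parameter vector of one
network (length L = i*k + k*j + k + j for an i-k-j architecture), its
fitness is the summed absolute prediction error of that network, and the
population evolves by roulette selection on inverse fitness, arithmetic
crossover, and annealed non-uniform mutation with one elite preserved
per generation.  The best chromosome seeds the gradient-descent run
(the GA-BP hybrid).

Default GA settings: population 20, crossover probability 0.8, mutation
probability 0.1, 50 generations, gene bounds [-1, 1].

Grid-search helpers reproduce the usual tuning studies over hidden-node
count, learning rate, and training-step (epoch) count using the
training-set MSE as the comparison metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Normalizer",
    "NetworkConfig",
    "NetworkParams",
    "Chromosome",
    "GAConfig",
    "normalize",
    "forward",
    "loss_and_gradients",
    "train_bp",
    "coding_length",
    "encode",
    "decode",
    "init_params",
    "fitness",
    "select_roulette",
    "crossover",
    "mutate",
    "run_ga",
    "train_ga_bp",
    "grid_search",
    "save_model",
    "load_model",
]

GENE_LAYOUT_VERSION = 1
EPS_SELECTION = 1e-12


# ---------------------------------------------------------------------------
# normalisation


@dataclass(frozen=True)
class Normalizer:
    """Affine min-max rescaling onto a target interval (default [-1, 1])."""

    x_min: float
    x_max: float
    target: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min:
            raise ValueError(
                f"degenerate range: x_max ({self.x_max}) must exceed x_min "
                f"({self.x_min})"
            )
        if self.target[1] <= self.target[0]:
            raise ValueError(f"target interval must be increasing: {self.target}")

    @classmethod
    def fit(cls, x: np.ndarray, target: tuple[float, float] = (-1.0, 1.0)) -> "Normalizer":
        return cls(float(np.min(x)), float(np.max(x)), target)

    def transform(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.target
        unit = (np.asarray(x, dtype=float) - self.x_min) / (self.x_max - self.x_min)
        return lo + unit * (hi - lo)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        lo, hi = self.target
        unit = (np.asarray(y, dtype=float) - lo) / (hi - lo)
        return self.x_min + unit * (self.x_max - self.x_min)


def normalize(x: np.ndarray, norm: Normalizer) -> np.ndarray:
    """Min-max rescale ``x``; the minimum maps to the target's lower end
    and the maximum to its upper end."""
    return norm.transform(x)


# ---------------------------------------------------------------------------
# network


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and training settings of the three-layer network."""

    n_input: int
    n_hidden: int
    n_output: int = 1
    hidden_activation: str = "logistic"  # "logistic" or "tanh"
    learning_rate: float = 0.14
    max_epochs: int = 200
    error_goal: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_hidden, self.n_output) < 1:
            raise ValueError("layer sizes must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.hidden_activation not in ("logistic", "tanh"):
            raise ValueError(
                f"unknown hidden_activation {self.hidden_activation!r}"
            )


@dataclass
class NetworkParams:
    """All weights and biases of a three-layer network."""

    w_in_hidden: np.ndarray  # (i, k)
    b_hidden: np.ndarray  # (k,)
    w_hidden_out: np.ndarray  # (k, j)
    b_out: np.ndarray  # (j,)

    def validate(self, config: NetworkConfig) -> None:
        i, k, j = config.n_input, config.n_hidden, config.n_output
        shapes = {
            "w_in_hidden": (self.w_in_hidden.shape, (i, k)),
            "b_hidden": (self.b_hidden.shape, (k,)),
            "w_hidden_out": (self.w_hidden_out.shape, (k, j)),
            "b_out": (self.b_out.shape, (j,)),
        }
        for name, (got, want) in shapes.items():
            if got != want:
                raise ValueError(f"{name} has shape {got}, expected {want}")

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.w_in_hidden.copy(),
            self.b_hidden.copy(),
            self.w_hidden_out.copy(),
            self.b_out.copy(),
        )

    @property
    def n_parameters(self) -> int:
        return (
            self.w_in_hidden.size
            + self.b_hidden.size
            + self.w_hidden_out.size
            + self.b_out.size
        )


def _activation(name: str):
    if name == "logistic":
        f = lambda z: 1.0 / (1.0 + np.exp(-z))
        df = lambda a: a * (1.0 - a)  # derivative in terms of the activation
    else:  # tanh
        f = np.tanh
        df = lambda a: 1.0 - a * a
    return f, df


def forward(
    params: NetworkParams, config: NetworkConfig, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass; accepts a single input vector or an (n, i) batch.

    Returns ``(output, hidden)`` with shapes matching the input layout.
    Hidden units apply the configured sigmoid; the output layer is linear
    so its range is unrestricted.
    """
    params.validate(config)
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xb = x[None, :] if single else x
    if xb.shape[1] != config.n_input:
        raise ValueError(
            f"input has {xb.shape[1]} features, expected {config.n_input}"
        )
    act, _ = _activation(config.hidden_activation)
    hidden = act(xb @ params.w_in_hidden + params.b_hidden)
    out = hidden @ params.w_hidden_out + params.b_out
    if single:
        return out[0], hidden[0]
    return out, hidden


def loss_and_gradients(
    params: NetworkParams,
    config: NetworkConfig,
    x: np.ndarray,
    y: np.ndarray,
) -> tuple[float, NetworkParams]:
    """Mean-squared-error loss and its exact gradients.

    The MSE is averaged over all samples and output nodes.  Output-layer
    deltas are the residuals (linear output); hidden-layer deltas
    back-propagate through the transposed output weights times the
    sigmoid derivative.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    out, hidden = forward(params, config, x)
    resid = out - y
    mse = float(np.mean(resid**2))
    scale = 2.0 / resid.size
    grad_out = scale * resid  # dL/d(out)
    _, dact = _activation(config.hidden_activation)
    delta_hidden = (grad_out @ params.w_hidden_out.T) * dact(hidden)
    grads = NetworkParams(
        w_in_hidden=x.T @ delta_hidden,
        b_hidden=delta_hidden.sum(axis=0),
        w_hidden_out=hidden.T @ grad_out,
        b_out=grad_out.sum(axis=0),
    )
    return mse, grads


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


def train_bp(
    params: NetworkParams,
    config: NetworkConfig,
    x: np.ndarray,
    y: np.ndarray,
) -> tuple[NetworkParams, list[float]]:
    """Full-batch gradient descent on MSE from the given initial params.

    Runs until ``max_epochs`` or until the error drops to ``error_goal``.
    Returns the trained parameters and the per-epoch error trace (the
    trace entry for an epoch is the MSE before that epoch's update, with
    the final MSE appended).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] == 0:
        raise ValueError("training data must be nonempty")
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite")
    p = params.copy()
    trace: list[float] = []
    lr = config.learning_rate
    for epoch in range(config.max_epochs):
        mse, g = loss_and_gradients(p, config, x, y)
        if not np.isfinite(mse):
            raise DivergenceError(f"non-finite training loss at epoch {epoch}")
        trace.append(mse)
        if mse <= config.error_goal:
            return p, trace
        p.w_in_hidden -= lr * g.w_in_hidden
        p.b_hidden -= lr * g.b_hidden
        p.w_hidden_out -= lr * g.w_hidden_out
        p.b_out -= lr * g.b_out
    final_mse, _ = loss_and_gradients(p, config, x, y)
    if not np.isfinite(final_mse):
        raise DivergenceError(f"non-finite training loss at epoch {config.max_epochs}")
    trace.append(final_mse)
    return p, trace


# ---------------------------------------------------------------------------
# chromosome coding


def coding_length(i: int, k: int, j: int) -> int:
    """Chromosome length for an i-k-j network: i*k + k*j + k + j."""
    if min(i, k, j) < 1:
        raise ValueError(f"layer sizes must be positive, got ({i}, {k}, {j})")
    return i * k + k * j + k + j


@dataclass
class Chromosome:
    """Real-valued genome: one full network parameter vector with bounds."""

    genes: np.ndarray
    bounds: tuple[float, float] = (-1.0, 1.0)
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=float)
        lo, hi = self.bounds
        if lo >= hi:
            raise ValueError(f"bounds must be increasing, got {self.bounds}")

    def copy(self) -> "Chromosome":
        return Chromosome(self.genes.copy(), self.bounds, self.fitness)


def encode(params: NetworkParams, bounds: tuple[float, float] = (-1.0, 1.0)) -> Chromosome:
    """Flatten parameters into a chromosome.

    Gene order (layout version 1): input-to-hidden weights row-major,
    hidden biases, hidden-to-output weights row-major, output biases.
    """
    genes = np.concatenate(
        [
            params.w_in_hidden.ravel(order="C"),
            params.b_hidden.ravel(),
            params.w_hidden_out.ravel(order="C"),
            params.b_out.ravel(),
        ]
    )
    return Chromosome(genes, bounds)


def decode(chromosome: Chromosome, config: NetworkConfig) -> NetworkParams:
    """Rebuild :class:`NetworkParams` from a chromosome (inverse of
    :func:`encode`); the gene count must match the coding length."""
    i, k, j = config.n_input, config.n_hidden, config.n_output
    expected = coding_length(i, k, j)
    genes = chromosome.genes
    if genes.size != expected:
        raise ValueError(
            f"chromosome has {genes.size} genes, expected {expected} for an "
            f"{i}-{k}-{j} network"
        )
    pos = 0

    def take(n: int) -> np.ndarray:
        nonlocal pos
        chunk = genes[pos : pos + n]
        pos += n
        return chunk.copy()

    return NetworkParams(
        w_in_hidden=take(i * k).reshape(i, k),
        b_hidden=take(k),
        w_hidden_out=take(k * j).reshape(k, j),
        b_out=take(j),
    )


def init_params(
    config: NetworkConfig,
    rng: np.random.Generator,
    bounds: tuple[float, float] = (-1.0, 1.0),
) -> NetworkParams:
    """Random parameters drawn uniformly within the gene bounds."""
    i, k, j = config.n_input, config.n_hidden, config.n_output
    lo, hi = bounds
    u = lambda *shape: rng.uniform(lo, hi, size=shape)
    return NetworkParams(u(i, k), u(k), u(k, j), u(j))


# ---------------------------------------------------------------------------
# genetic algorithm


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 20
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    max_generations: int = 50
    fitness_coefficient: float = 1.0  # the multiplier k in F = k * sum|y - a|
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_prob", "mutation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fitness_coefficient <= 0:
            raise ValueError("fitness_coefficient must be positive")


def fitness(
    chromosome: Chromosome,
    config: NetworkConfig,
    x: np.ndarray,
    y: np.ndarray,
    k_f: float = 1.0,
) -> float:
    """Summed absolute prediction error of the decoded network, times k_f.

    Smaller is better; zero means perfect prediction.  Non-finite
    predictions yield infinite fitness (worst possible).
    """
    params = decode(chromosome, config)
    out, _ = forward(params, config, np.atleast_2d(np.asarray(x, dtype=float)))
    err = np.abs(np.atleast_2d(np.asarray(y, dtype=float)) - out).sum()
    if not np.isfinite(err):
        return float("inf")
    return float(k_f * err)


def select_roulette(
    population: Sequence[Chromosome],
    rng: np.random.Generator,
    n: int | None = None,
    eps: float = EPS_SELECTION,
) -> list[Chromosome]:
    """Roulette selection on a minimised fitness.

    Selection scores are the inverse fitnesses 1/(F + eps), so the
    individual with the smallest fitness has the highest selection
    probability, and individuals are drawn with replacement with
    probability proportional to their score.
    """
    if not population:
        raise ValueError("population is empty")
    if any(c.fitness is None for c in population):
        raise ValueError("all individuals must have evaluated fitness")
    n = len(population) if n is None else n
    fits = np.array([c.fitness for c in population], dtype=float)
    scores = np.where(np.isfinite(fits), 1.0 / (fits + eps), 0.0)
    if scores.sum() == 0:  # every individual diverged: fall back to uniform
        probs = np.full(len(population), 1.0 / len(population))
    else:
        probs = scores / scores.sum()
    picks = rng.choice(len(population), size=n, replace=True, p=probs)
    return [population[i].copy() for i in picks]


def crossover(
    parent_a: Chromosome,
    parent_b: Chromosome,
    crossover_prob: float,
    rng: np.random.Generator,
    blend: float | None = None,
    positions: np.ndarray | None = None,
) -> tuple[Chromosome, Chromosome]:
    """Symmetric arithmetic crossover.

    With probability ``crossover_prob`` a set of crossover positions is
    drawn (each gene independently with probability 1/2) and the two
    children take the convex blends ``a*(1-b) + b'*b`` and symmetrically,
    with a single blend factor b ~ U[0, 1]; otherwise the children are
    plain copies.  Convexity keeps children inside the gene bounds.
    ``blend``/``positions`` inject deterministic values for testing.
    """
    if parent_a.genes.size != parent_b.genes.size:
        raise ValueError("parents must have equal length")
    child_a, child_b = parent_a.copy(), parent_b.copy()
    child_a.fitness = child_b.fitness = None
    if rng.random() >= crossover_prob:
        return child_a, child_b
    if positions is None:
        positions = rng.random(parent_a.genes.size) < 0.5
    b = rng.uniform() if blend is None else float(blend)
    ga, gb = parent_a.genes[positions], parent_b.genes[positions]
    child_a.genes[positions] = ga * (1.0 - b) + gb * b
    child_b.genes[positions] = gb * (1.0 - b) + ga * b
    return child_a, child_b


def mutate(
    chromosome: Chromosome,
    mutation_prob: float,
    generation: int,
    max_generations: int,
    rng: np.random.Generator,
    printed_convention: bool = False,
) -> Chromosome:
    """Non-uniform mutation annealed over generations.

    Each gene mutates with probability ``mutation_prob``.  A direction
    draw r decides the branch: for r > 0.5 the gene moves toward the
    upper bound, otherwise toward the lower bound, by the fraction
    f(g) = r2 * (1 - g/G)^2 of the remaining distance (r2 ~ U[0, 1]), so
    the perturbation shrinks to zero by the final generation and the
    result always stays within bounds.

    ``printed_convention=True`` flips the sign of the upper branch to
    ``a + (a - a_max) * f`` (which moves away from the upper bound and can
    undershoot), with the result clipped back into the bounds.
    """
    if generation > max_generations:
        raise ValueError(
            f"generation ({generation}) must not exceed max_generations "
            f"({max_generations})"
        )
    out = chromosome.copy()
    out.fitness = None
    lo, hi = out.bounds
    anneal = (1.0 - generation / max_generations) ** 2
    for idx in range(out.genes.size):
        if rng.random() >= mutation_prob:
            continue
        r = rng.random()
        f_g = rng.random() * anneal
        a = out.genes[idx]
        if r > 0.5:
            step = (a - hi) * f_g if printed_convention else (hi - a) * f_g
        else:
            step = (lo - a) * f_g
        out.genes[idx] = np.clip(a + step, lo, hi)
    return out


def run_ga(
    ga_config: GAConfig,
    fitness_fn: Callable[[np.ndarray], float],
    n_genes: int,
    bounds: tuple[float, float] = (-1.0, 1.0),
    rng: np.random.Generator | None = None,
) -> tuple[Chromosome, list[float]]:
    """Evolve a population against ``fitness_fn`` (smaller is better).

    Runs exactly ``max_generations`` generations of roulette selection,
    arithmetic crossover and annealed mutation, with one elite: the best
    individual found so far replaces the worst child each generation, so
    the best-fitness trace is non-increasing.  Returns the overall best
    chromosome and the per-generation best-fitness trace.
    """
    if rng is None:
        rng = np.random.default_rng(ga_config.seed)
    lo, hi = bounds
    population = [
        Chromosome(rng.uniform(lo, hi, size=n_genes), bounds)
        for _ in range(ga_config.population_size)
    ]
    for c in population:
        c.fitness = fitness_fn(c.genes)
    best = min(population, key=lambda c: c.fitness).copy()

    trace: list[float] = []
    for g in range(1, ga_config.max_generations + 1):
        pool = select_roulette(population, rng)
        children: list[Chromosome] = []
        for a_idx in range(0, len(pool) - 1, 2):
            ca, cb = crossover(
                pool[a_idx], pool[a_idx + 1], ga_config.crossover_prob, rng
            )
            children.extend([ca, cb])
        if len(pool) % 2:  # odd population: last individual passes through
            children.append(pool[-1])
        children = [
            mutate(c, ga_config.mutation_prob, g, ga_config.max_generations, rng)
            for c in children
        ]
        for c in children:
            c.fitness = fitness_fn(c.genes)
        # elitism: the stored optimum replaces the worst child
        worst = max(range(len(children)), key=lambda idx: children[idx].fitness)
        if best.fitness < children[worst].fitness:
            children[worst] = best.copy()
        population = children
        gen_best = min(population, key=lambda c: c.fitness)
        if gen_best.fitness < best.fitness:
            best = gen_best.copy()
        trace.append(best.fitness)
    return best, trace


def train_ga_bp(
    ga_config: GAConfig,
    net_config: NetworkConfig,
    x: np.ndarray,
    y: np.ndarray,
    bounds: tuple[float, float] = (-1.0, 1.0),
) -> tuple[NetworkParams, list[float], list[float]]:
    """GA-BP hybrid: evolve initial weights, then refine by gradient descent.

    Returns (trained params, GA best-fitness trace, BP error trace).
    With ``max_generations=0`` the GA reduces to drawing the initial
    population and picking its best member.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    length = coding_length(net_config.n_input, net_config.n_hidden, net_config.n_output)
    rng = np.random.default_rng(ga_config.seed)

    def fit_fn(genes: np.ndarray) -> float:
        return fitness(
            Chromosome(genes, bounds), net_config, x, y, ga_config.fitness_coefficient
        )

    if ga_config.max_generations == 0:
        lo, hi = bounds
        population = [
            Chromosome(rng.uniform(lo, hi, size=length), bounds)
            for _ in range(ga_config.population_size)
        ]
        for c in population:
            c.fitness = fit_fn(c.genes)
        best, ga_trace = min(population, key=lambda c: c.fitness), []
    else:
        best, ga_trace = run_ga(ga_config, fit_fn, length, bounds, rng)
    params0 = decode(best, net_config)
    trained, bp_trace = train_bp(params0, net_config, x, y)
    return trained, ga_trace, bp_trace


# ---------------------------------------------------------------------------
# hyperparameter grids

GRID_AXES = ("hidden_nodes", "learning_rate", "step_size")


def grid_search(
    net_config: NetworkConfig,
    x: np.ndarray,
    y: np.ndarray,
    axis: str,
    values: Sequence[float],
    seed: int = 0,
) -> tuple[list[tuple[float, float]], float]:
    """Train one plain-BP network per grid value and tabulate final MSE.

    ``axis`` is one of ``hidden_nodes``, ``learning_rate`` or
    ``step_size`` (training epochs); all other settings are held at the
    template's values and every grid point shares the same seed so the
    comparison is paired.  Returns the (value, error) table and the
    argmin value.
    """
    if axis not in GRID_AXES:
        raise ValueError(f"axis must be one of {GRID_AXES}, got {axis!r}")
    if len(values) == 0:
        raise ValueError("grid is empty")
    table: list[tuple[float, float]] = []
    for v in values:
        if axis == "hidden_nodes":
            cfg = replace(net_config, n_hidden=int(v))
        elif axis == "learning_rate":
            cfg = replace(net_config, learning_rate=float(v))
        else:
            cfg = replace(net_config, max_epochs=int(v))
        rng = np.random.default_rng(seed)
        params0 = init_params(cfg, rng)
        _, trace = train_bp(params0, cfg, x, y)
        table.append((float(v), trace[-1]))
    best_value = min(table, key=lambda t: t[1])[0]
    return table, best_value


# ---------------------------------------------------------------------------
# model persistence


def save_model(
    path: str,
    params: NetworkParams,
    config: NetworkConfig,
    ga_trace: Sequence[float] = (),
    bp_trace: Sequence[float] = (),
) -> None:
    """Write the model as round-trip-loadable JSON."""
    chrom = encode(params)
    payload = {
        "gene_layout_version": GENE_LAYOUT_VERSION,
        "config": {
            "n_input": config.n_input,
            "n_hidden": config.n_hidden,
            "n_output": config.n_output,
            "hidden_activation": config.hidden_activation,
            "learning_rate": config.learning_rate,
            "max_epochs": config.max_epochs,
            "error_goal": config.error_goal,
        },
        "genes": chrom.genes.tolist(),
        "ga_trace": list(map(float, ga_trace)),
        "bp_trace": list(map(float, bp_trace)),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path: str) -> tuple[NetworkParams, NetworkConfig, dict]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("gene_layout_version") != GENE_LAYOUT_VERSION:
        raise ValueError("unsupported gene layout version")
    config = NetworkConfig(**payload["config"])
    params = decode(Chromosome(np.asarray(payload["genes"])), config)
    return params, config, payload
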