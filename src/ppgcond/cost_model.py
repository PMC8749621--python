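"""Analytic operation-count cost model for conditioner variants.

Real-time feasibility on a wearable is judged by counting the basic
arithmetic operations one inference performs, weighted by their measured
relative costs (normalised to one addition): add 1, subtract 1,
multiply 1.2, divide 3, exp 15.  The sigmoid and tanh nonlinearities are
expanded into those basic operations literally:

    sigmoid(x) = 1 / (1 + e^(-x))      -> 1 sub (negate) + 1 exp + 1 add
                                          + 1 div         = 20 units
    tanh(x) = (e^x - e^(-x)) / (e^x + e^(-x))
                                       -> 2 exp + 2 sub + 1 add + 1 div
                                                          = 36 units

Per LSTM timestep with input width ``d`` and hidden size ``h``, the four
gate pre-activations cost ``h(d+h)`` multiplies and ``h(d+h)`` adds
each; the gate activations cost ``3h`` sigmoids and ``h`` tanh; the cell
update costs ``2h`` multiplies + ``h`` adds; the hidden-state update
costs ``h`` tanh + ``h`` multiplies.  A network variant is costed with
the flattened convention ``d = 4L``, ``h = N_h * N_l`` over ``L``
timesteps plus the linear output head (``h`` multiplies + ``h`` adds);
an exact per-layer mode is available as an alternative.

The closed-form counts are cross-checked against an oracle that runs a
scalar-arithmetic LSTM step instrumented to count every basic operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .lstm import ModelConfig

__all__ = [
    "CostTable",
    "CostBreakdown",
    "OpCounter",
    "sigma_cost",
    "tanh_cost",
    "lstm_step_cost",
    "lstm_step_cost_oracle",
    "variant_cost",
]


@dataclass(frozen=True)
class CostTable:
    """Relative costs of the basic operations (add is the unit)."""

    add: float = 1.0
    subtract: float = 1.0
    multiply: float = 1.2
    divide: float = 3.0
    exp: float = 15.0

    def validate(self) -> None:
        for name in ("add", "subtract", "multiply", "divide", "exp"):
            if not getattr(self, name) > 0:
                raise ValueError(f"cost of {name} must be positive")


@dataclass
class CostBreakdown:
    """Basic-operation counts of one LSTM timestep and their weighted total."""

    d: int
    h: int
    add: int = 0
    subtract: int = 0
    multiply: int = 0
    divide: int = 0
    exp: int = 0
    sigma_count: int = 0
    tanh_count: int = 0
    total_relative_cost: float = 0.0

    def basic_counts(self) -> dict[str, int]:
        """Counts with sigma/tanh expanded into basic operations."""
        return {
            "add": self.add + self.sigma_count + self.tanh_count,
            "subtract": self.subtract + self.sigma_count + 2 * self.tanh_count,
            "multiply": self.multiply,
            "divide": self.divide + self.sigma_count + self.tanh_count,
            "exp": self.exp + self.sigma_count + 2 * self.tanh_count,
        }


def sigma_cost(table: CostTable) -> float:
    """Weighted cost of one sigmoid: negate, exp, add, divide."""
    table.validate()
    return table.subtract + table.exp + table.add + table.divide


def tanh_cost(table: CostTable) -> float:
    """Weighted cost of one tanh: 2 exp, negate + numerator subtract,
    denominator add, divide."""
    table.validate()
    return 2.0 * table.exp + 2.0 * table.subtract + table.add + table.divide


def lstm_step_cost(d: int, h: int, table: CostTable) -> CostBreakdown:
    """Closed-form operation counts of one LSTM timestep."""
    if d < 1 or h < 1:
        raise ValueError("d and h must be >= 1")
    table.validate()
    # four gate pre-activations: W x (h*d mult, h*(d-1) add), U h_prev
    # (h*h mult, h*(h-1) add), two vector adds (+U term, +bias): 2h add
    gate_mult = h * d + h * h
    gate_add = h * (d - 1) + h * (h - 1) + 2 * h
    bd = CostBreakdown(d=d, h=h)
    bd.multiply = 4 * gate_mult
    bd.add = 4 * gate_add
    bd.sigma_count = 3 * h  # input, forget, output gates
    bd.tanh_count = h  # cell input activation
    # cell state: f*c + i*g -> 2h mult + h add
    bd.multiply += 2 * h
    bd.add += h
    # hidden state: o * tanh(c) -> h tanh + h mult
    bd.tanh_count += h
    bd.multiply += h
    bd.total_relative_cost = (
        table.add * bd.add
        + table.subtract * bd.subtract
        + table.multiply * bd.multiply
        + table.divide * bd.divide
        + table.exp * bd.exp
        + sigma_cost(table) * bd.sigma_count
        + tanh_cost(table) * bd.tanh_count
    )
    return bd


# ---------------------------------------------------------------------------
# instrumented scalar oracle
# ---------------------------------------------------------------------------

class OpCounter:
    """Scalar arithmetic that counts every basic operation it performs."""

    def __init__(self) -> None:
        self.counts = {"add": 0, "subtract": 0, "multiply": 0, "divide": 0, "exp": 0}

    def add(self, a, b):
        self.counts["add"] += 1
        return a + b

    def sub(self, a, b):
        self.counts["subtract"] += 1
        return a - b

    def mul(self, a, b):
        self.counts["multiply"] += 1
        return a * b

    def div(self, a, b):
        self.counts["divide"] += 1
        return a / b

    def exp(self, a):
        import math

        self.counts["exp"] += 1
        return math.exp(a)

    # nonlinearities built from the basic operations
    def sigmoid(self, x):
        return self.div(1.0, self.add(1.0, self.exp(self.sub(0.0, x))))

    def tanh(self, x):
        ex = self.exp(x)
        enx = self.exp(self.sub(0.0, x))
        return self.div(self.sub(ex, enx), self.add(ex, enx))

    def dot_plus(self, w_row, x, u_row, hvec, b):
        """w_row . x + u_row . h + b as counted scalar operations."""
        acc = self.mul(w_row[0], x[0])
        for wj, xj in zip(w_row[1:], x[1:]):
            acc = self.add(acc, self.mul(wj, xj))
        acc2 = self.mul(u_row[0], hvec[0])
        for uj, hj in zip(u_row[1:], hvec[1:]):
            acc2 = self.add(acc2, self.mul(uj, hj))
        return self.add(self.add(acc, acc2), b)

    def weighted_total(self, table: CostTable) -> float:
        return (
            table.add * self.counts["add"]
            + table.subtract * self.counts["subtract"]
            + table.multiply * self.counts["multiply"]
            + table.divide * self.counts["divide"]
            + table.exp * self.counts["exp"]
        )


def lstm_step_cost_oracle(d: int, h: int, seed: int = 0) -> OpCounter:
    """Execute one LSTM timestep in counted scalar arithmetic.

    Runs the full recurrence (four gates, cell update, hidden update) on
    random numbers, counting every basic operation performed.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    x = rng.standard_normal(d).tolist()
    h_prev = rng.standard_normal(h).tolist()
    c_prev = rng.standard_normal(h).tolist()
    W = rng.standard_normal((4, h, d)).tolist()
    U = rng.standard_normal((4, h, h)).tolist()
    b = rng.standard_normal((4, h)).tolist()

    ops = OpCounter()
    gates = []
    for gate in range(4):
        pre = [
            ops.dot_plus(W[gate][j], x, U[gate][j], h_prev, b[gate][j])
            for j in range(h)
        ]
        if gate == 2:  # cell input activation uses tanh
            gates.append([ops.tanh(p) for p in pre])
        else:
            gates.append([ops.sigmoid(p) for p in pre])
    i_g, f_g, g_g, o_g = gates
    c_new = [
        ops.add(ops.mul(f_g[j], c_prev[j]), ops.mul(i_g[j], g_g[j]))
        for j in range(h)
    ]
    _h_new = [ops.mul(o_g[j], ops.tanh(c_new[j])) for j in range(h)]
    return ops


def variant_cost(
    config: ModelConfig, table: CostTable | None = None, exact_layers: bool = False
) -> float:
    """Total relative cost of one inference of a network variant.

    Default convention: ``d = 4L``, ``h = N_h * N_l``, ``L`` timesteps,
    plus the linear output head.  ``exact_layers=True`` instead costs
    each layer with its true input width (layer 1: d = 4; layer k > 1:
    d = N_h), which is exact for stacked two-layer networks.
    """
    if table is None:
        table = CostTable()
    head = table.multiply * config.n_hidden + table.add * config.n_hidden
    if exact_layers:
        total = 0.0
        d = 4
        for _ in range(config.n_layers):
            total += config.L * lstm_step_cost(d, config.n_hidden, table).total_relative_cost
            d = config.n_hidden
        return total + head
    d = 4 * config.L
    h = config.n_hidden * config.n_layers
    return config.L * lstm_step_cost(d, h, table).total_relative_cost + head
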