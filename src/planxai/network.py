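"""Two-head recurrent policy/value network over DVH inputs.

The agent observes only the 300-value DVH vector, so plan-parameter tuning
is a partially observed decision process; an LSTM cell carries a memory of
past observations.  Architecture:

    dvh (300) -> dense tanh (64) -> LSTM cell (32) -> policy head (18, softmax)
                                                   -> Q head (18, linear)

The LSTM cell is the standard gated recurrence

    f = sigmoid(W_if u + U_hf h + b_f)        (forget gate)
    i = sigmoid(W_ii u + U_hi h + b_i)        (input gate)
    g = tanh   (W_ig u + U_hg h + b_g)        (cell candidate)
    o = sigmoid(W_io u + U_ho h + b_o)        (output gate)
    c_t = f * c + i * g
    h_t = o * tanh(c_t)

so the network receives three inputs at each step: the DVH vector and the
previous memory states c and h.  Forward and backward passes are written
directly in numpy; the backward pass returns exact analytic gradients both
with respect to the three inputs (for path-integral attribution) and with
respect to all parameters (for training).  All operations support a leading
batch axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_ACTIONS = 18
DVH_DIM = 300

GATE_NAMES = ("f", "i", "g", "o")
PARAM_KEYS = (
    ["W1", "b1"]
    + [f"W{g}" for g in GATE_NAMES] + [f"U{g}" for g in GATE_NAMES]
    + [f"b{g}" for g in GATE_NAMES]
    + ["Wp", "bp", "Wq", "bq"]
)


@dataclass(frozen=True)
class MemoryState:
    """LSTM memory: long-term cell vector c and hidden vector h."""

    c: np.ndarray
    h: np.ndarray

    def __post_init__(self):
        if not (np.all(np.isfinite(self.c)) and np.all(np.isfinite(self.h))):
            raise ValueError("memory state contains non-finite entries")


@dataclass(frozen=True)
class PolicyOutput:
    probs: np.ndarray       # 18 action probabilities
    q_values: np.ndarray    # 18 state-action values
    new_memory: MemoryState


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class PolicyValueNet:
    """Holds the parameter dict and implements forward/backward passes."""

    def __init__(self, params: dict[str, np.ndarray]):
        self.params = params
        self.hidden = params["Wf"].shape[0]
        self.dense = params["W1"].shape[0]
        self.input_dim = params["W1"].shape[1]

    # -- construction -----------------------------------------------------
    @classmethod
    def init(cls, seed: int, input_dim: int = DVH_DIM, dense: int = 64,
             hidden: int = 32, n_actions: int = N_ACTIONS) -> "PolicyValueNet":
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4E7]))
        def mat(rows, cols):
            return rng.normal(0.0, 1.0 / np.sqrt(cols), size=(rows, cols))
        p: dict[str, np.ndarray] = {"W1": mat(dense, input_dim),
                                    "b1": np.zeros(dense)}
        for g in GATE_NAMES:
            p[f"W{g}"] = mat(hidden, dense)
            p[f"U{g}"] = mat(hidden, hidden)
            p[f"b{g}"] = np.zeros(hidden)
        p["bf"] = np.ones(hidden)  # forget-gate bias init
        p["Wp"] = mat(n_actions, hidden)
        p["bp"] = np.zeros(n_actions)
        p["Wq"] = mat(n_actions, hidden)
        p["bq"] = np.zeros(n_actions)
        return cls(p)

    @classmethod
    def zeros(cls, input_dim: int = DVH_DIM, dense: int = 64,
              hidden: int = 32, n_actions: int = N_ACTIONS) -> "PolicyValueNet":
        net = cls.init(0, input_dim, dense, hidden, n_actions)
        net.params = {k: np.zeros_like(v) for k, v in net.params.items()}
        return net

    def copy(self) -> "PolicyValueNet":
        return PolicyValueNet({k: v.copy() for k, v in self.params.items()})

    def zero_memory(self) -> MemoryState:
        return MemoryState(c=np.zeros(self.hidden), h=np.zeros(self.hidden))

    # -- forward ----------------------------------------------------------
    def forward(self, dvh: np.ndarray, memory: MemoryState) -> PolicyOutput:
        """Single-step forward pass (unbatched convenience wrapper)."""
        cache = self.forward_cache(dvh[None, :], memory.c[None, :],
                                   memory.h[None, :])
        if not np.all(np.isfinite(cache["p"])):
            raise FloatingPointError("non-finite policy output")
        return PolicyOutput(
            probs=cache["p"][0], q_values=cache["q"][0],
            new_memory=MemoryState(c=cache["c_t"][0], h=cache["h_t"][0]))

    def forward_cache(self, X: np.ndarray, C: np.ndarray,
                      H: np.ndarray) -> dict[str, np.ndarray]:
        """Batched forward pass keeping intermediates for backprop.

        X: (B, input_dim), C and H: (B, hidden).
        """
        p = self.params
        u = np.tanh(X @ p["W1"].T + p["b1"])
        f = _sigmoid(u @ p["Wf"].T + H @ p["Uf"].T + p["bf"])
        i = _sigmoid(u @ p["Wi"].T + H @ p["Ui"].T + p["bi"])
        g = np.tanh(u @ p["Wg"].T + H @ p["Ug"].T + p["bg"])
        o = _sigmoid(u @ p["Wo"].T + H @ p["Uo"].T + p["bo"])
        c_t = f * C + i * g
        tanh_c = np.tanh(c_t)
        h_t = o * tanh_c
        logits = h_t @ p["Wp"].T + p["bp"]
        probs = softmax(logits)
        q = h_t @ p["Wq"].T + p["bq"]
        return {"X": X, "C": C, "H": H, "u": u, "f": f, "i": i, "g": g,
                "o": o, "c_t": c_t, "tanh_c": tanh_c, "h_t": h_t,
                "logits": logits, "p": probs, "q": q}

    # -- backward ---------------------------------------------------------
    def backward(self, cache: dict[str, np.ndarray], dlogits: np.ndarray,
                 dq: np.ndarray | None = None, *, want_params: bool = False):
        """Backpropagate through one step.

        Returns ``(dX, dC, dH)`` and, if ``want_params``, also the
        parameter-gradient dict (summed over the batch).
        """
        p = self.params
        h_t = cache["h_t"]
        dh = dlogits @ p["Wp"]
        if dq is not None:
            dh = dh + dq @ p["Wq"]
        o, tanh_c, f, i, g = (cache[k] for k in ("o", "tanh_c", "f", "i", "g"))
        do = dh * tanh_c
        dc = dh * o * (1.0 - tanh_c ** 2)
        dC = dc * f
        dzf = (dc * cache["C"]) * f * (1.0 - f)
        dzi = (dc * g) * i * (1.0 - i)
        dzg = (dc * i) * (1.0 - g ** 2)
        dzo = do * o * (1.0 - o)
        du = dzf @ p["Wf"] + dzi @ p["Wi"] + dzg @ p["Wg"] + dzo @ p["Wo"]
        dH = dzf @ p["Uf"] + dzi @ p["Ui"] + dzg @ p["Ug"] + dzo @ p["Uo"]
        dz1 = du * (1.0 - cache["u"] ** 2)
        dX = dz1 @ p["W1"]
        if not want_params:
            return dX, dC, dH
        u, H, X = cache["u"], cache["H"], cache["X"]
        grads = {"W1": dz1.T @ X, "b1": dz1.sum(axis=0),
                 "Wp": dlogits.T @ h_t, "bp": dlogits.sum(axis=0)}
        if dq is not None:
            grads["Wq"] = dq.T @ h_t
            grads["bq"] = dq.sum(axis=0)
        else:
            grads["Wq"] = np.zeros_like(p["Wq"])
            grads["bq"] = np.zeros_like(p["bq"])
        for name, dz in zip(GATE_NAMES, (dzf, dzi, dzg, dzo)):
            grads[f"W{name}"] = dz.T @ u
            grads[f"U{name}"] = dz.T @ H
            grads[f"b{name}"] = dz.sum(axis=0)
        return (dX, dC, dH), grads

    def prob_input_gradients(self, X: np.ndarray, C: np.ndarray,
                             H: np.ndarray, action: int):
        """Batched gradients of the post-softmax probability of ``action``
        with respect to the three inputs.

        Returns ``(probs, dX, dC, dH)`` where ``probs`` is (B, 18) and the
        gradients have the shapes of the inputs.
        """
        cache = self.forward_cache(X, C, H)
        probs = cache["p"]
        onehot = np.zeros(probs.shape[1])
        onehot[action] = 1.0
        dlogits = probs[:, action:action + 1] * (onehot[None, :] - probs)
        dX, dC, dH = self.backward(cache, dlogits)
        return probs, dX, dC, dH
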