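"""Conservative sub-stepped integrator for a network of water stores.

Nodes hold water (mm per ground area) and expose their potential and
capacitance as functions of content; edges carry flux proportional to the
potential difference (minus a gravity head) through a state-dependent
conductance.

Each sub-step is integrated with backward Euler: the pair fluxes are
evaluated at the end-of-step state found by a small damped Newton iteration
(conductances frozen per iteration, potentials linearized through the nodal
capacitances). The implicit treatment keeps low-capacitance nodes such as
the leaf on their quasi-steady through-flow solution at hourly steps, where
an explicit scheme would either oscillate or starve them. A trial step over
the full interval sets the number of sub-steps so that no node's relative
content change exceeds the configured fraction per sub-step.

Water is conserved by construction: the converged pair fluxes are applied
antisymmetrically, and every external addition/removal is tallied in the
returned totals.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

Array = np.ndarray


@dataclasses.dataclass
class Node:
    name: str
    psi_of: Callable[[Array], Array]   # water potential (MPa) from content (mm)
    cap_of: Callable[[Array], Array]   # capacitance dW/dpsi (mm MPa-1), > 0
    w_min: Array                        # lower content bound (mm)
    w_max: Array                        # upper content bound (mm)


@dataclasses.dataclass
class Edge:
    i: int                              # upstream node index
    j: int                              # downstream node index
    conductance: Callable[[Array, Array], Array]  # K(psi_i, psi_j), mm h-1 MPa-1
    head: float = 0.0                   # gravity head (MPa) opposing i -> j flow


class WaterNetwork:
    """Water-store network with optional fused state/conductance evaluators.

    ``eval_state(W) -> (psi, caps)`` and ``edge_conds(psi) -> [K per edge]``
    may be supplied to evaluate all nodes/edges in a few vectorized calls;
    they must agree with the per-node/per-edge callables, which remain the
    reference implementation.
    """

    def __init__(self, nodes: Sequence[Node], edges: Sequence[Edge],
                 max_frac_change: float = 0.02, max_substeps: int = 30,
                 newton_iters: int = 5, newton_tol: float = 1e-6,
                 eval_state=None, edge_conds=None):
        self.nodes = list(nodes)
        self.edges = list(edges)
        self.max_frac_change = max_frac_change
        self.max_substeps = max_substeps
        self.newton_iters = newton_iters
        self.newton_tol = newton_tol
        self._eval_state = eval_state
        self._edge_conds = edge_conds
        # a pure chain (every edge links k to k+1) has a tridiagonal Jacobian
        self._is_chain = all(e.j == e.i + 1 for e in self.edges) and \
            len({e.i for e in self.edges}) == len(self.edges)
        self._warm_nsub = 1

    def validate_state(self, W: Array) -> None:
        for k, node in enumerate(self.nodes):
            if np.any(W[k] < node.w_min - 1e-9) or np.any(W[k] > node.w_max + 1e-9):
                raise ValueError(
                    f"node '{node.name}' content outside bounds before stepping")

    def potentials(self, W: Array) -> Array:
        if self._eval_state is not None:
            return self._eval_state(np.asarray(W, float))[0]
        return np.stack([node.psi_of(np.asarray(W[k], float))
                         for k, node in enumerate(self.nodes)])

    def _state(self, W: Array):
        if self._eval_state is not None:
            return self._eval_state(W)
        psi = np.stack([node.psi_of(np.asarray(W[k], float))
                        for k, node in enumerate(self.nodes)])
        caps = np.stack([node.cap_of(np.asarray(W[k], float))
                         for k, node in enumerate(self.nodes)])
        return psi, caps

    def _conds(self, psi: Array) -> list:
        if self._edge_conds is not None:
            return self._edge_conds(psi)
        return [np.asarray(e.conductance(psi[e.i], psi[e.j]), float)
                for e in self.edges]

    def _newton_step_chain(self, x, W, S, dts):
        """One Newton update using the tridiagonal (chain) Jacobian."""
        n = len(self.nodes)
        psi, caps = self._state(x)
        conds = self._conds(psi)
        F = np.zeros_like(x)
        diag = [np.ones_like(x[0]) for _ in range(n)]
        upper = [np.zeros_like(x[0]) for _ in range(n - 1)]
        lower = [np.zeros_like(x[0]) for _ in range(n - 1)]
        for e, K in zip(self.edges, conds):
            q = K * (psi[e.i] - psi[e.j] - e.head)
            F[e.i] -= q
            F[e.j] += q
            ki = dts * K / caps[e.i]
            kj = dts * K / caps[e.j]
            diag[e.i] = diag[e.i] + ki
            diag[e.j] = diag[e.j] + kj
            upper[e.i] = -kj
            lower[e.i] = -ki
        R = [x[k] - W[k] - dts * (F[k] + S[k]) for k in range(n)]
        # Thomas elimination, vectorized over members
        for k in range(1, n):
            w = lower[k - 1] / diag[k - 1]
            diag[k] = diag[k] - w * upper[k - 1]
            R[k] = R[k] - w * R[k - 1]
        step = np.empty_like(x)
        step[n - 1] = R[n - 1] / diag[n - 1]
        for k in range(n - 2, -1, -1):
            step[k] = (R[k] - upper[k] * step[k + 1]) / diag[k]
        return x - step, float(np.max(np.abs(step)))

    def _newton_step_dense(self, x, W, S, dts):
        n = len(self.nodes)
        flat = W[0].ndim == 0
        m = 1 if flat else W.shape[1]
        psi, caps = self._state(x)
        conds = self._conds(psi)
        F = np.zeros_like(x)
        J = np.zeros((m, n, n))
        J[:, range(n), range(n)] = 1.0
        for e, K in zip(self.edges, conds):
            q = K * (psi[e.i] - psi[e.j] - e.head)
            F[e.i] -= q
            F[e.j] += q
            ki = dts * K / caps[e.i]
            kj = dts * K / caps[e.j]
            J[:, e.i, e.i] += ki
            J[:, e.i, e.j] -= kj
            J[:, e.j, e.i] -= ki
            J[:, e.j, e.j] += kj
        R = x - W - dts * (F + S)
        step = np.linalg.solve(J, R.reshape(n, m).T[:, :, None])[:, :, 0].T
        step = step.reshape(x.shape)
        return x - step, float(np.max(np.abs(step)))

    def _implicit_substep(self, W: Array, S: Array, dts: float):
        """Backward-Euler sub-step; returns the new contents (conservative)."""
        newton = self._newton_step_chain if self._is_chain \
            else self._newton_step_dense
        x = W.copy()
        for _ in range(self.newton_iters):
            x, step_norm = newton(x, W, S, dts)
            if step_norm < self.newton_tol:
                break
        # conservative update: apply the implicit-state fluxes antisymmetrically
        psi, _caps = self._state(x)
        conds = self._conds(psi)
        W_new = W + dts * S
        for e, K in zip(self.edges, conds):
            tr = K * (psi[e.i] - psi[e.j] - e.head) * dts
            W_new[e.i] -= tr
            W_new[e.j] += tr
        return W_new

    def step(self, W: Array, dt: float, ext_fn=None):
        """Advance the network by dt (hours).

        ``ext_fn(W, psi)`` returns a list of ``(name, node_index, rate)``
        external fluxes in mm h-1, positive into the node. Overshoot above a
        node's capacity is removed and tallied as ``overflow_<node>``
        (saturation excess on the soil store); content pinned at the lower
        bound is restored and tallied as ``clamp_<node>``.

        Returns ``(W_new, totals, n_sub, n_clamp)`` where totals maps each
        external-flux name (and overflow/clamp entries) to accumulated mm.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        W0 = np.array(W, dtype=float)
        self.validate_state(W0)
        span = np.stack([np.broadcast_to(node.w_max - node.w_min, W0[k].shape)
                         for k, node in enumerate(self.nodes)])
        span = np.maximum(span, 1e-12)

        def run(n_sub: int):
            Wc = W0.copy()
            dts = dt / n_sub
            totals: dict[str, Array] = {}
            n_clamp = 0
            max_frac = 0.0
            for _ in range(n_sub):
                psi, _caps = self._state(Wc)
                S = np.zeros_like(Wc)
                if ext_fn is not None:
                    for name, k, rate in ext_fn(Wc, psi):
                        S[k] = S[k] + rate
                        totals[name] = totals.get(name, 0.0) + rate * dts
                W_prev = Wc
                Wc = self._implicit_substep(Wc, S, dts)
                max_frac = max(max_frac,
                               float(np.max(np.abs(Wc - W_prev) / span)))
                for k, node in enumerate(self.nodes):
                    over = np.maximum(Wc[k] - node.w_max, 0.0)
                    if np.any(over > 0):
                        Wc[k] = Wc[k] - over
                        totals[f"overflow_{node.name}"] = \
                            totals.get(f"overflow_{node.name}", 0.0) + over
                    under = np.maximum(node.w_min - Wc[k], 0.0)
                    if np.any(under > 1e-12):
                        n_clamp += int(np.count_nonzero(under > 1e-12))
                        Wc[k] = Wc[k] + under
                        totals[f"clamp_{node.name}"] = \
                            totals.get(f"clamp_{node.name}", 0.0) + under
            return Wc, totals, n_clamp, max_frac

        # trial (warm-started from the previous call's sub-step count);
        # redo finer if the max-relative-change rule broke
        n_try = min(self._warm_nsub, self.max_substeps)
        W_new, totals, n_clamp, max_frac = run(n_try)
        n_sub = n_try
        if max_frac > self.max_frac_change and n_try < self.max_substeps:
            n_sub = int(np.clip(np.ceil(n_try * max_frac / self.max_frac_change),
                                n_try + 1, self.max_substeps))
            W_new, totals, n_clamp, _ = run(n_sub)
        # decay toward a single sub-step when conditions calm down
        self._warm_nsub = n_sub if max_frac > self.max_frac_change \
            else max(1, n_sub // 2)
        return W_new, totals, n_sub, n_clamp
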