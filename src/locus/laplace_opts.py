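"""Optimiser settings for the Laplace inversion scheme."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FitOptions:
    """Newton-scheme controls.

    tolerance             -- convergence when the free-energy gain of an
                             accepted step falls below this (nats).
    fd_step               -- central-difference step in unconstrained space.
    initial_damping       -- Levenberg-Marquardt damping added to the negative
                             Hessian; doubled on a rejected step, halved on an
                             accepted one.
    """

    max_iterations: int = 128
    tolerance: float = 1e-4
    # 1e-3 balances truncation against cancellation error: these likelihoods
    # are smooth at unit scale, and a smaller step makes the finite-difference
    # Hessian rounding-noise-limited
    fd_step: float = 1e-3
    initial_damping: float = 1e-3
    min_damping: float = 1e-8
    max_damping_doublings: int = 24
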