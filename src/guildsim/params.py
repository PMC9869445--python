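"""Core model parameters.

The model tracks discrete cultural traits ("tools") held by a guild of N
individuals.  Per time step each individual invents a tool with probability
``p_inv``; a new tool establishes with probability equal to its selection
coefficient s ~ Exponential(mean ``beta``), clamped to 1.  An established tool
is lost per step with probability ``(p_loss / N) * c**t``, where t is the
guild's current repertoire size: the ``c**t`` factor encodes the finite
individual capacity for knowledge (remembering and transmitting a large
repertoire gets harder as it grows).

In the two-environment extension, a fraction ``env_specific_fraction`` of
newly established tools is only useful in the environment it was invented in;
whenever the current environment differs, such a tool's per-step loss
probability is multiplied by ``env_loss_multiplier``.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ModelParams"]


@dataclass(frozen=True)
class ModelParams:
    """Rates and constants of the innovation-loss model.

    Parameters
    ----------
    p_inv:
        Invention probability per individual per time step, in [0, 1].
    p_loss:
        Baseline loss scale (> 0); per-tool loss is ``p_loss / N`` before
        capacity scaling.
    beta:
        Mean of the exponential distribution of selection coefficients (> 0);
        a new tool establishes with probability min(s, 1), s ~ Exp(beta).
    c:
        Capacity base (>= 1); per-tool loss is multiplied by ``c**t``.
        ``c == 1`` recovers the capacity-free model.
    env_specific_fraction:
        Probability that a newly established tool is specific to the current
        environment (two-environment model only).
    env_loss_multiplier:
        Loss-probability multiplier (>= 1) applied to environment-specific
        tools while the environment is mismatched.
    """

    p_inv: float = 0.001
    p_loss: float = 0.002
    beta: float = 0.1
    c: float = 1.001
    env_specific_fraction: float = 0.9
    env_loss_multiplier: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_inv <= 1.0:
            raise ValueError(f"p_inv must be in [0, 1], got {self.p_inv}")
        if not self.p_loss > 0.0:
            raise ValueError(f"p_loss must be > 0, got {self.p_loss}")
        if not self.beta > 0.0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not self.c >= 1.0:
            raise ValueError(f"c must be >= 1, got {self.c}")
        if not 0.0 <= self.env_specific_fraction <= 1.0:
            raise ValueError(
                "env_specific_fraction must be in [0, 1], got "
                f"{self.env_specific_fraction}"
            )
        if not self.env_loss_multiplier >= 1.0:
            raise ValueError(
                f"env_loss_multiplier must be >= 1, got {self.env_loss_multiplier}"
            )
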