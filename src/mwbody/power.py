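"""Study-design helpers."""

import math

from statsmodels.stats.power import TTestPower


def required_sample_size(
    effect_size: float = 0.5,
    alpha: float = 0.05,
    power: float = 0.8,
    alternative: str = "two-sided",
) -> int:
    """Minimum n for a one-sample / paired t test via the noncentral-t method.

    With the conventional medium effect (d = 0.5), alpha = .05 two-tailed and
    80% power this gives 34 participants.
    """
    n = TTestPower().solve_power(
        effect_size=effect_size, alpha=alpha, power=power, alternative=alternative
    )
    return math.ceil(n)
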