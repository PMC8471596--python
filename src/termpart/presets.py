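"""Packaged generating parameters for the terminator plate screen.

Each :class:`~termpart.synthetic_data.ConstructParams` entry encodes the
published screen outcome for one construct x strain combination in the
cw15 host under zeocin selection: the Poisson colony-count mean
(colonies/µg), the per-round survival probabilities (geometric split of
the reported round-3 marginal: each round's conditional survival is the
cube root of the final viability), and the GFP-positive probability
among round-3 survivors.

Printed anchors used directly:

* RBCS2 (baseline): 2.47e3 colonies/µg; 74% viable at round 3; 23% GFP+.
* CA1: 5.50e3 colonies/µg; 13-point viability reduction (87% viable);
  81% GFP+.
* PSAD: 83% GFP+.
* no-3'UTR control: 1.63e3 colonies/µg; ~45% viable; 25% GFP+.

Where only a range was published (PSAD/THI4/METE/NIT1 efficiencies, the
20-32% viability reductions of the non-CA1 terminators, the 15-35% and
60-70% GFP bands of the short and long groups), mid-range values are
used; those entries are provided for end-to-end pipeline runs and back
no quantitative anchor.

The deferred-selection workflow preset models the alternative regime of
three non-selective subcultures (95/96 of lines surviving overall)
followed by two rounds under zeocin ending at 49% viability.
"""

from __future__ import annotations

from termpart.synthetic_data import ConstructParams, ScreenGenConfig

__all__ = [
    "paper_screen_preset",
    "paper_screen_config",
    "deferred_selection_preset",
    "deferred_selection_config",
    "PAPER_CONSTRUCTS",
]


def _geometric_split(final_viability: float, n_rounds: int = 3) -> tuple[float, ...]:
    p = final_viability ** (1.0 / n_rounds)
    return (p,) * n_rounds


PAPER_CONSTRUCTS: dict[str, ConstructParams] = {
    cp.construct: cp
    for cp in [
        ConstructParams("RBCS2", "cw15", 2470.0, _geometric_split(0.74), 0.23),
        ConstructParams("no3UTR", "cw15", 1630.0, _geometric_split(0.45), 0.25),
        ConstructParams("CA1", "cw15", 5500.0, _geometric_split(0.87), 0.81),
        ConstructParams("PSAD", "cw15", 3200.0, _geometric_split(0.75), 0.83),
        ConstructParams("THI4", "cw15", 3000.0, _geometric_split(0.72), 0.65),
        ConstructParams("METE", "cw15", 3100.0, _geometric_split(0.70), 0.65),
        ConstructParams("NIT1", "cw15", 2900.0, _geometric_split(0.70), 0.65),
        ConstructParams("RPS29", "cw15", 2100.0, _geometric_split(0.70), 0.32),
        ConstructParams("RPL11", "cw15", 2100.0, _geometric_split(0.70), 0.25),
        ConstructParams("RPL31", "cw15", 2000.0, _geometric_split(0.70), 0.20),
    ]
}


def paper_screen_preset(constructs: list[str] | None = None) -> list[ConstructParams]:
    """The packaged cw15/zeocin screen parameters, optionally restricted
    to named constructs."""
    if constructs is None:
        return list(PAPER_CONSTRUCTS.values())
    return [PAPER_CONSTRUCTS[c] for c in constructs]


def paper_screen_config(
    constructs: list[str] | None = None,
    seed: int = 0,
    n_experiments: int = 3,
    n_lines: int = 96,
) -> ScreenGenConfig:
    """Screen-generator config at study scale: 3 independent experiments
    of 96 lines each, 6 technical colony-count plates, 1 µg DNA."""
    return ScreenGenConfig(
        constructs=paper_screen_preset(constructs),
        n_experiments=n_experiments,
        n_lines=n_lines,
        n_technical=6,
        dna_ug=1.0,
        seed=seed,
    )


def deferred_selection_preset() -> ConstructParams:
    """The no-selection-first workflow: three non-selective rounds whose
    joint survival is 95/96, then two zeocin rounds ending at 49%
    overall viability (equal conditional survival per selective round)."""
    p_ns = (95.0 / 96.0) ** (1.0 / 3.0)
    p_sel = (0.49 / (95.0 / 96.0)) ** 0.5
    return ConstructParams(
        construct="RBCS2",
        strain="cw15",
        efficiency_mean=2470.0,
        survival_probs=(p_ns, p_ns, p_ns, p_sel, p_sel),
        gfp_prob=0.23,
        selection="deferred_zeocin",
    )


def deferred_selection_config(seed: int = 0, n_experiments: int = 3) -> ScreenGenConfig:
    return ScreenGenConfig(
        constructs=[deferred_selection_preset()],
        n_experiments=n_experiments,
        n_lines=96,
        n_technical=6,
        dna_ug=1.0,
        seed=seed,
    )
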