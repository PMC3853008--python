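"""Epidemiologic parameters of the five-state model.

The base-case values are national estimates for US adults aged 20+: annual
diabetes incidence of 0.3% from normal glucose, 2.4% from IFG without IGT,
and 3.9% from IFG with IGT; mortality relative risks (vs. no diabetes) of
1.77 for undiagnosed and 2.11 for diagnosed diabetes; and 2007 prevalences
of 12.9% total diabetes, 26.7% IFG (regardless of IGT), and 8.3% IFG+IGT.

Detection, diagnosed-at-onset, progression, and the incidence scale are not
directly observed; they are solved by :mod:`dmpolicy.calibration`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

# Printed base-case inputs (annual probabilities / fractions).
LAMBDA_NORMAL = 0.003
LAMBDA_IFG = 0.024
LAMBDA_IFG_IGT = 0.039
OVERALL_INCIDENCE = 0.0122
RR_UNDIAG = 1.77
RR_DIAG = 2.11

PREV_DM_2007 = 0.129
PREV_IFG_ANY_2007 = 0.267
PREV_IFG_IGT_2007 = 0.083

#: Diagnosed share of total diabetes, taken from the 2030 ratio 16.3/22.7 —
#: the only year for which the split is printed; the model holds it stable.
DIAGNOSED_SHARE_DEFAULT = 16.3 / 22.7


@dataclass(frozen=True)
class EpidemiologicParameters:
    """Transition-rate parameters of the model (all annual probabilities).

    ``incidence_scale`` multiplies the three stratum incidences jointly; it
    absorbs the gap between the printed stratum rates (which average to
    ~1.09%/yr over the 2007 population) and the overall 1.22%/yr incidence
    the model is meant to start from.  ``incidence_growth`` is a constant
    annual multiplicative trend on incidence: 1.0 is the flat-trend
    background scenario.
    """

    lambda_normal: float = LAMBDA_NORMAL
    lambda_ifg: float = LAMBDA_IFG
    lambda_ifgigt: float = LAMBDA_IFG_IGT
    overall_incidence: float = OVERALL_INCIDENCE
    rr_undiag: float = RR_UNDIAG
    rr_diag: float = RR_DIAG
    detection_rate: float = 0.0
    diagnosed_at_onset_fraction: float = 0.0
    prog_normal_to_ifg: float = 0.0
    prog_ifg_to_ifgigt: float = 0.0
    incidence_scale: float = 1.0
    incidence_growth: float = 1.0

    def __post_init__(self) -> None:
        probs = {
            "lambda_normal": self.lambda_normal,
            "lambda_ifg": self.lambda_ifg,
            "lambda_ifgigt": self.lambda_ifgigt,
            "detection_rate": self.detection_rate,
            "diagnosed_at_onset_fraction": self.diagnosed_at_onset_fraction,
            "prog_normal_to_ifg": self.prog_normal_to_ifg,
            "prog_ifg_to_ifgigt": self.prog_ifg_to_ifgigt,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        # strict risk gradient across strata; an all-zero (no-incidence)
        # configuration is allowed for degenerate/test dynamics
        lams = (self.lambda_normal, self.lambda_ifg, self.lambda_ifgigt)
        if any(v > 0 for v in lams) and not lams[0] < lams[1] < lams[2]:
            raise ValueError(
                "stratum incidences must be ordered normal < IFG < IFG+IGT"
            )
        for name in ("rr_undiag", "rr_diag", "incidence_scale", "incidence_growth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_(self, **kwargs) -> "EpidemiologicParameters":
        return replace(self, **kwargs)

    @property
    def stratum_incidence(self):
        """Unscaled incidence per non-diabetes state, matrix order."""
        return (self.lambda_normal, self.lambda_ifg, self.lambda_ifgigt)


@dataclass(frozen=True)
class PrevalenceInputs:
    """Printed 2007 prevalence fractions used to build the initial state."""

    year: int = 2007
    total_dm_rate: float = PREV_DM_2007
    ifg_rate_any: float = PREV_IFG_ANY_2007
    ifg_igt_rate: float = PREV_IFG_IGT_2007
    diagnosed_share_of_dm: float = DIAGNOSED_SHARE_DEFAULT

    def __post_init__(self) -> None:
        if self.ifg_igt_rate > self.ifg_rate_any:
            raise ValueError("IFG+IGT prevalence cannot exceed IFG prevalence")
        if self.total_dm_rate + self.ifg_rate_any >= 1.0:
            raise ValueError("diabetes plus IFG prevalence must be below 1")
        if not 0.0 <= self.diagnosed_share_of_dm <= 1.0:
            raise ValueError("diagnosed_share_of_dm outside [0, 1]")
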