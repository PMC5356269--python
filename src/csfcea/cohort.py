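"""Diagnostic-accuracy algebra for the tested cohort.

The tested population is patients referred with suspected dementia who remain
without a definitive diagnosis after clinical assessment and MR neuroimaging.
Pure closed-form probability identities link the observed proportion
diagnosed, the true prevalence in the referral population, the prevalence in
the residual (MRI-negative) cohort, and the conditional accuracy of CSF
biomarker analysis in that cohort. Probabilities are carried at full
precision; percentage rounding happens only in reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Accuracy",
    "DiagnosticOutcomeProbs",
    "referral_prevalence",
    "post_mri_prevalence",
    "memory_subcohort_prevalence",
    "conditional_biomarker_accuracy",
    "outcome_probabilities",
]


@dataclass(frozen=True)
class Accuracy:
    """Plain sensitivity/specificity pair (floats, no sampling metadata)."""

    sn: float
    sp: float

    def __post_init__(self):
        if not (0.0 <= self.sn <= 1.0 and 0.0 <= self.sp <= 1.0):
            raise ValueError(f"sensitivity/specificity must be in [0,1]: {self}")


@dataclass(frozen=True)
class DiagnosticOutcomeProbs:
    """Probability of each diagnostic outcome in the tested cohort."""

    p_tp: float
    p_fn: float
    p_fp: float
    p_tn: float

    def __post_init__(self):
        total = self.p_tp + self.p_fn + self.p_fp + self.p_tn
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"outcome probabilities sum to {total!r}, not 1")
        for name, v in self.as_dict().items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {"TP": self.p_tp, "FN": self.p_fn, "FP": self.p_fp, "TN": self.p_tn}

    @property
    def prevalence(self) -> float:
        return self.p_tp + self.p_fn


def referral_prevalence(proportion_diagnosed: float, acc: Accuracy) -> float:
    """True disease prevalence in the referral population.

    Inverts ``proportion diagnosed = prevalence * sensitivity
    + (1 - prevalence) * (1 - specificity)``: the observed diagnosis rate is a
    mixture of true positives and false positives of the clinical-plus-MRI
    criterion.
    """
    if acc.sn + acc.sp <= 1.0:
        raise ValueError("uninformative test: requires sn + sp > 1")
    lo, hi = 1.0 - acc.sp, acc.sn
    if not (lo - 1e-12 <= proportion_diagnosed <= hi + 1e-12):
        raise ValueError(
            f"proportion diagnosed {proportion_diagnosed} outside the attainable "
            f"interval [{lo}, {hi}] for sn={acc.sn}, sp={acc.sp}")
    return min(1.0, max(0.0, (proportion_diagnosed - lo) / (hi - lo)))


def post_mri_prevalence(referral_p: float, mr: Accuracy,
                        fraction_nonad_excluded: float = 0.0) -> float:
    """Prevalence among patients still undiagnosed after clinical + MRI work-up.

    Patients with disease missed by the criterion (``p * (1 - sn)``) remain, as
    do non-diseased patients not falsely diagnosed (``(1 - p) * sp``), of whom
    a fraction may be removed by an alternative definitive (non-AD) diagnosis.
    """
    for name, v in [("referral_p", referral_p),
                    ("fraction_nonad_excluded", fraction_nonad_excluded)]:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} = {v} outside [0, 1]")
    miss = referral_p * (1.0 - mr.sn)
    stay = (1.0 - referral_p) * mr.sp * (1.0 - fraction_nonad_excluded)
    denom = miss + stay
    if denom == 0.0:
        raise ValueError("empty residual cohort (denominator 0)")
    return miss / denom


def memory_subcohort_prevalence(referral_p: float, mem: Accuracy,
                                mr_combined: Accuracy) -> float:
    """Prevalence among patients positive on memory impairment alone but
    negative on the combined clinical + MRI criterion.

    This is the cohort actually considered for biomarker analysis when
    patients without memory impairment are excluded: memory impairment casts a
    wider net (higher sensitivity, lower specificity) than the combined
    criterion, and the difference isolates the biomarker-candidate subcohort.
    """
    d_sn = mem.sn - mr_combined.sn
    d_fp = (1.0 - mem.sp) - (1.0 - mr_combined.sp)
    if d_sn < 0 or d_fp < 0:
        raise ValueError("memory-impairment criterion must be at least as "
                         "sensitive and no more specific than the combined criterion")
    num = referral_p * d_sn
    denom = num + (1.0 - referral_p) * d_fp
    if denom == 0.0:
        raise ValueError("empty subcohort: criteria are identical")
    return num / denom


def conditional_biomarker_accuracy(combined: Accuracy, mr: Accuracy) -> Accuracy:
    """Accuracy of biomarker analysis conditional on a negative MRI criterion.

    Solves the serial-testing identities
    ``sn_combined = sn_mr + (1 - sn_mr) * sn_bm`` and
    ``sp_combined = sp_mr * sp_bm``: under the revised criteria a patient is
    positive if MRI or biomarkers are positive, so biomarkers only act on the
    MRI-negative stratum.
    """
    if combined.sn < mr.sn:
        raise ValueError("identity sn_combined = sn_mr + (1 - sn_mr) * sn_bm "
                         "requires sn_combined >= sn_mr")
    if mr.sp <= 0.0:
        raise ValueError("identity sp_combined = sp_mr * sp_bm requires sp_mr > 0")
    if combined.sp > mr.sp:
        raise ValueError("identity sp_combined = sp_mr * sp_bm requires "
                         "sp_combined <= sp_mr")
    if mr.sn >= 1.0:
        sn_bm = 0.0
    else:
        sn_bm = (combined.sn - mr.sn) / (1.0 - mr.sn)
    sp_bm = combined.sp / mr.sp
    return Accuracy(sn=sn_bm, sp=sp_bm)


def outcome_probabilities(prevalence: float, bm: Accuracy) -> DiagnosticOutcomeProbs:
    """Split the tested cohort into TP/FN/FP/TN by prevalence and test accuracy."""
    if not (0.0 <= prevalence <= 1.0):
        raise ValueError(f"prevalence {prevalence} outside [0, 1]")
    return DiagnosticOutcomeProbs(
        p_tp=prevalence * bm.sn,
        p_fn=prevalence * (1.0 - bm.sn),
        p_fp=(1.0 - prevalence) * (1.0 - bm.sp),
        p_tn=(1.0 - prevalence) * bm.sp,
    )
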