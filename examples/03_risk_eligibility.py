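"""Score risk-factor profiles and apply the 5% five-year-risk gate.

Builds three profiles of increasing exposure, converts each to a 5-year
absolute lung-cancer risk by scaling age/sex incidence with the logistic
relative risk, and prints who clears the screening eligibility gate.
"""

from lungscreen.cohort import RiskFactorProfile
from lungscreen.risk import default_coefficients, default_incidence, score_profiles

profiles = {
    "light_ex_smoker_55": RiskFactorProfile(
        age=55, sex="female", smoking_status="ex", smoking_duration=8,
        asbestos_exposure=False, respiratory_disease=False,
        prior_malignancy=False, family_history="none",
    ),
    "long_smoker_63": RiskFactorProfile(
        age=63, sex="male", smoking_status="current", smoking_duration=40,
        asbestos_exposure=False, respiratory_disease=False,
        prior_malignancy=False, family_history="none",
    ),
    "heavy_exposure_70": RiskFactorProfile(
        age=70, sex="male", smoking_status="current", smoking_duration=50,
        asbestos_exposure=True, respiratory_disease=True,
        prior_malignancy=False, family_history="early",
    ),
}

scored = score_profiles(
    profiles.values(), default_coefficients(), default_incidence(), mean_rr=5.0
)
scored.insert(0, "profile", list(profiles))
print(scored.to_string(index=False))
print()
print(
    "absolute_risk_5yr is the chance of lung cancer in the next five years;\n"
    "subjects at or above 0.05 are eligible for LDCT screening."
)
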