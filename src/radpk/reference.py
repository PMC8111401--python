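"""Reference parameter values for lisinopril disposition in adult rats.

Point estimates from a population analysis of single-dose lisinopril in
female WAG/RijCmcr rats, 35 days after 12.5-13 Gy partial-body irradiation
(one hind leg spared) or sham treatment.  ``CONTROL_PARAMS`` are the typical
values in non-irradiated animals; ``RADIATION_RATIOS`` are the multiplicative
irradiated/control effects on absorption rate, renal clearance,
inter-compartmental clearance and bioavailability.  They serve both as
worked-example inputs and as the default generating values of the synthetic
study simulator.
"""

from .core_model import PKParameters, RadiationEffect

__all__ = ["CONTROL_PARAMS", "RADIATION_RATIOS"]

#: Typical two-compartment parameters in non-irradiated rats:
#: ka 0.279 /h, F 0.192, Cl 0.009 L/h, Q 0.014 L/h, V2 0.008 L, V3 0.513 L.
CONTROL_PARAMS = PKParameters(ka=0.279, F=0.192, Cl=0.009, Q=0.014, V2=0.008, V3=0.513)

#: Irradiated/control multiplicative effects on ka, Cl, Q and F.
RADIATION_RATIOS = RadiationEffect(r_ka=0.883, r_Cl=0.943, r_Q=0.615, r_F=1.326)
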