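"""Efficiency-corrected relative qPCR quantification (Pfaffl method).

ChIP enrichment of a target locus is quantified against an internal
standard locus: for each locus x,

    dCt_x = Ct_input,x - Ct_IP,x

with the input Ct first corrected for the input-sample dilution
(subtracting log_E of the dilution factor, since a 1:d diluted input
crosses threshold log_E(d) cycles later than undiluted material), and

    fold = E_target ** dCt_target / E_reference ** dCt_reference.

Amplification efficiencies are accepted in the 95-105% band by default
(E in [1.95, 2.05]); out-of-band efficiencies raise unless overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["QpcrEnrichment", "pfaffl"]

EFFICIENCY_BAND = (1.95, 2.05)


@dataclass
class QpcrEnrichment:
    """Ct values and efficiencies for one target/reference ChIP-qPCR pair."""

    ct_ip_target: float
    ct_input_target: float
    ct_ip_ref: float
    ct_input_ref: float
    e_target: float = 2.0
    e_ref: float = 2.0
    dilution: float = 1.0     # input dilution factor, >= 1 (100 for a 1:100 input)

    def __post_init__(self):
        for name in ("ct_ip_target", "ct_input_target", "ct_ip_ref", "ct_input_ref"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"missing or non-finite Ct value: {name}")
        if self.dilution < 1:
            raise ValueError("dilution is a factor >= 1 (e.g. 100 for a 1:100 input)")

    @property
    def dct_target(self) -> float:
        return (self.ct_input_target - math.log(self.dilution, self.e_target)) - self.ct_ip_target

    @property
    def dct_ref(self) -> float:
        return (self.ct_input_ref - math.log(self.dilution, self.e_ref)) - self.ct_ip_ref


def pfaffl(enr: QpcrEnrichment, enforce_efficiency_band: bool = True) -> float:
    """Fold enrichment of the target in IP DNA relative to the reference.

    Raises if an efficiency falls outside the accepted band unless
    ``enforce_efficiency_band=False``.
    """
    if enforce_efficiency_band:
        lo, hi = EFFICIENCY_BAND
        for name, e in (("target", enr.e_target), ("reference", enr.e_ref)):
            if not (lo <= e <= hi):
                raise ValueError(
                    f"{name} efficiency {e} outside accepted band [{lo}, {hi}];"
                    " pass enforce_efficiency_band=False to override"
                )
    return enr.e_target ** enr.dct_target / enr.e_ref ** enr.dct_ref
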