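"""Reference parameter sets and study designs.

Best-fit values from cynomolgus-monkey PK studies of a therapeutic IgG4
antibody (half-life ~11.5 days): a single 10 mg/kg IV dose sampled over 56
days, and a 3 mg/kg dose every 14 days sampled over the same span.  These
are the package's worked-example inputs and the default generating
parameters for the synthetic-data module, so that every analysis stage can
be exercised end to end without external data.

Rates follow the package-wide convention: PTM rate constants are fractions
per day (a rate quoted as "0.5394% per day" is 0.005394 here), PK rates are
1/day, concentrations ug/mL, times days.
"""

from __future__ import annotations

from .multidose import DoseRegimen
from .pk import BiexponentialParams
from .ptm import FirstOrderPTMParams

__all__ = [
    "SINGLE_DOSE_PK",
    "MULTI_DOSE_PK",
    "ASN_SITE_1",
    "ASN_SITE_2",
    "ASN_SITE_3",
    "PYROGLUTAMATE",
    "PTM_SITES",
    "SINGLE_DOSE_SAMPLING_DAYS",
    "MULTI_DOSE_FIRST_INTERVAL_DAYS",
    "MULTI_DOSE_PREPOST_DAYS",
    "BIWEEKLY_5_DOSES",
    "STUDY_WINDOW_DAYS",
    "GOOD_FIT_R2",
]

#: Single-dose serum-concentration fit (ug/mL and 1/day).
SINGLE_DOSE_PK = BiexponentialParams(A=139.0925, B=180.8075, alpha=1.1227, beta=0.0389)

#: First-interval fit from the repeated-dose study.  Note the fast and slow
#: roles of alpha and beta are swapped relative to the single-dose fit; the
#: model is symmetric in its two terms so no reordering is applied.
MULTI_DOSE_PK = BiexponentialParams(A=57.8676, B=25.3133, alpha=0.0413, beta=0.9286)

# First-order modification kinetics per site (fractions and fraction/day).
ASN_SITE_1 = FirstOrderPTMParams(p0=0.001918, k=0.00003523, site="Asn site 1")
ASN_SITE_2 = FirstOrderPTMParams(p0=0.01143, k=0.005394, site="Asn site 2")
ASN_SITE_3 = FirstOrderPTMParams(p0=0.008848, k=0.001546, site="Asn site 3")
PYROGLUTAMATE = FirstOrderPTMParams(p0=0.006868, k=0.002201, site="N-terminal pyroglutamate")

PTM_SITES = {p.site: p for p in (ASN_SITE_1, ASN_SITE_2, ASN_SITE_3, PYROGLUTAMATE)}

#: Single-dose collection schedule: pre-dose, 5 min, 4 h, 12 h, then days.
SINGLE_DOSE_SAMPLING_DAYS = (
    0.0, 5.0 / 1440.0, 4.0 / 24.0, 0.5, 1.0, 3.0, 7.0, 14.0, 18.0, 30.0, 42.0, 56.0,
)

#: Repeated-dose schedule: within the first interval (post-dose, 1 h, 4 h,
#: days 1, 3, 7) ...
MULTI_DOSE_FIRST_INTERVAL_DAYS = (0.0, 1.0 / 24.0, 4.0 / 24.0, 1.0, 3.0, 7.0)
#: ... then trough/peak pairs at each subsequent dose.
MULTI_DOSE_PREPOST_DAYS = (14.0, 28.0, 42.0, 56.0)

BIWEEKLY_5_DOSES = DoseRegimen(tau=14.0, n_doses=5)
STUDY_WINDOW_DAYS = 56.0

#: R^2 at or above this is considered a good fit.
GOOD_FIT_R2 = 0.95
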