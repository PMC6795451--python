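# pqakin

Modeling of *in vivo* post-translational modification (PTM) kinetics and
subject exposure to product quality attributes (PQAs) of therapeutic
monoclonal antibodies, for bioanalytical scientists running single- and
multiple-dose PK studies.

After administration, an antibody keeps chemically changing in circulation:
asparagine residues deamidate, the N-terminus cyclizes to pyroglutamate.
Whether such a quality attribute matters for safety or efficacy depends on
how much of it the subject is actually exposed to over time. `pqakin`
quantifies that from two measured curves:

- the total serum concentration, fit to a two-compartment IV-bolus model
  `C(t) = A·e^(−αt) + B·e^(−βt)`;
- the modified fraction at a site, fit to the first-order law
  `P(t) = 1 − (1 − P0)·e^(−kt)`.

The variant concentration is their product, `C_pqa(t) = C(t)·P(t)`, and the
subject exposure to the variant is its AUC, available in closed form. Under
repeated dosing every τ days the package predicts trough (pre-dose) and
peak (post-dose) concentrations and modified levels by linear
superposition, including their closed-form steady states, e.g. the
steady-state trough `C_ss,pre = A/(e^(ατ)−1) + B/(e^(βτ)−1)` and the
corresponding age-weighted steady-state PTM level.

The package also covers the two ends of the pipeline: reduction of
LC-MS peptide peak areas to percent-modified time series (EIC ratio of the
modified peptide over modified + native, with a capture-recovery QC check),
and a synthetic-study generator used to validate every stage end to end.

## Worked example

Reference parameter sets from cynomolgus-monkey studies of an IgG4
antibody ship with the package:

```python
import numpy as np
from pqakin import reference as R
from pqakin import (auc_trapezoid, concentration_at, pqa_exposure,
                    steady_state_concentration, steady_state_pqa_level)

# single-dose exposure to drug deamidated at "Asn site 2" over 56 days
s = pqa_exposure(R.SINGLE_DOSE_PK, R.ASN_SITE_2, 0.0, 56.0)
print(f"{s.pqa_auc:.1f} ug/mL*day ({100 * s.fraction:.1f}% of total)")

# total exposure on the 12-point study sampling grid
t = np.asarray(R.SINGLE_DOSE_SAMPLING_DAYS)
print(f"{auc_trapezoid(t, concentration_at(R.SINGLE_DOSE_PK, t)):.1f} ug/mL*day")

# biweekly dosing: steady-state trough concentration and PTM level
print(f"{steady_state_concentration(R.MULTI_DOSE_PK, 14.0, 'pre'):.1f} ug/mL")
print(f"{100 * steady_state_pqa_level(R.MULTI_DOSE_PK, R.ASN_SITE_2, 14.0, 'pre'):.1f} %")
```

prints

```
426.2 ug/mL*day (10.0% of total)
4308.6 ug/mL*day
73.9 ug/mL
16.1 %
```

i.e. about a tenth of the 56-day drug exposure is carried by molecules
deamidated at that site, and under biweekly dosing the trough-level
deamidation plateaus at ~16% once accumulation reaches steady state.

The two curve fits are scikit-learn estimators (`BiexponentialPKModel`,
`FirstOrderPTMModel`) and compose with sklearn tooling; `fit_biexponential`
and `fit_first_order_ptm` are convenience wrappers. A `pqakin` CLI exposes
the pipeline (`fit-pk`, `fit-ptm`, `quantify`, `exposure`, `cdr-scenario`,
`predict-multidose`, `steady-state`, `simulate`); run `pqakin --help`.

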