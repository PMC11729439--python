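# Baseline (healthy-stratum) mean and standard deviation for every
# examination feature, on the units routinely reported by hospital
# laboratories. These set the scale of the synthetic cohort only; the
# statistical structure (which strata carry which effects) is controlled
# by the cohort specification.
RR:        {mean: 18.0,  sd: 3.0}    # breaths/min
SBP:       {mean: 132.0, sd: 16.0}   # mmHg
NT-proBNP: {mean: 320.0, sd: 180.0}  # pg/mL
PLT:       {mean: 240.0, sd: 60.0}   # 1e9/L
RBC:       {mean: 4.4,   sd: 0.5}    # 1e12/L
WBC:       {mean: 6.8,   sd: 1.9}    # 1e9/L
RDW-CV:    {mean: 13.4,  sd: 1.2}    # %
RDW-SD:    {mean: 42.0,  sd: 3.5}    # fL
MCHC:      {mean: 338.0, sd: 11.0}   # g/L
MCH:       {mean: 30.0,  sd: 2.0}    # pg
MCV:       {mean: 90.0,  sd: 5.0}    # fL
HCT:       {mean: 0.40,  sd: 0.04}   # fraction
HB:        {mean: 132.0, sd: 15.0}   # g/L
USG:       {mean: 1.015, sd: 0.005}  # specific gravity
UPh:       {mean: 6.0,   sd: 0.7}    # pH
UWBC:      {mean: 5.0,   sd: 3.0}    # /uL
URBC:      {mean: 3.0,   sd: 2.0}    # /uL
EQRWC:     {mean: 10.0,  sd: 5.0}    # /uL equivalent
EQWBC:     {mean: 12.0,  sd: 6.0}    # /uL equivalent
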