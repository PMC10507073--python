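# Readmission knowledge base: 17 clinical concepts (12 low-frequency lab tests,
# 5 high-frequency chart items) with knowledge-based state cutoffs, the minimal
# change Delta regarded as a real trend, and the window (hours) within which a
# sub-threshold change counts as Stable.
#
# States are half-open, lower-inclusive intervals [min, max). Concept order in
# this file is the canonical tie-break order used when flattening simultaneous
# events. itemid is the synthetic-table convention (labs 50001.., charts 20001..).
concepts:
  - name: chloride
    source: lab
    unit: mEq/L
    itemid: 50001
    states: [{name: Low, max: 96.0}, {name: Normal, min: 96.0, max: 106.0}, {name: High, min: 106.0}]
    gradient_delta: 5.0
    stable_hours: 36.0
  - name: creatinine
    source: lab
    unit: mg/dL
    itemid: 50002
    states: [{name: Low, max: 0.6}, {name: Normal, min: 0.6, max: 1.3}, {name: High, min: 1.3}]
    gradient_delta: 0.2
    stable_hours: 36.0
  - name: glucose
    source: lab
    unit: mg/dL
    itemid: 50003
    states: [{name: Low, max: 70.0}, {name: Normal, min: 70.0, max: 100.0}, {name: High, min: 100.0}]
    gradient_delta: 10.0
    stable_hours: 36.0
  - name: hemoglobin
    source: lab
    unit: g/dL
    itemid: 50004
    states: [{name: Low, max: 11.0}, {name: Normal, min: 11.0, max: 18.0}, {name: High, min: 18.0}]
    gradient_delta: 2.0
    stable_hours: 36.0
  - name: pco2
    source: lab
    unit: mm Hg
    itemid: 50005
    states: [{name: Low, max: 38.0}, {name: Normal, min: 38.0, max: 42.0}, {name: High, min: 42.0}]
    gradient_delta: 2.0
    stable_hours: 36.0
  - name: ph
    source: lab
    unit: pH
    itemid: 50006
    states: [{name: Low, max: 7.34}, {name: Normal, min: 7.34, max: 7.45}, {name: High, min: 7.45}]
    gradient_delta: 0.05
    stable_hours: 36.0
  - name: phosphate
    source: lab
    unit: mg/dL
    itemid: 50007
    states: [{name: Low, max: 2.4}, {name: Normal, min: 2.4, max: 4.1}, {name: High, min: 4.1}]
    gradient_delta: 0.5
    stable_hours: 36.0
  - name: plt
    source: lab
    unit: 10^9/L
    itemid: 50008
    states: [{name: Low, max: 150.0}, {name: Normal, min: 150.0, max: 400.0}, {name: High, min: 400.0}]
    gradient_delta: 50.0
    stable_hours: 36.0
  - name: po2
    source: lab
    unit: torr
    itemid: 50009
    states: [{name: Low, max: 75.0}, {name: Normal, min: 75.0, max: 100.0}, {name: High, min: 100.0}]
    gradient_delta: 10.0
    stable_hours: 36.0
  - name: urea
    source: lab
    unit: mg/dL
    itemid: 50010
    states: [{name: Low, max: 10.0}, {name: Normal, min: 10.0, max: 20.0}, {name: High, min: 20.0}]
    gradient_delta: 5.0
    stable_hours: 36.0
  - name: sodium
    source: lab
    unit: mEq/L
    itemid: 50011
    states: [{name: Low, max: 135.0}, {name: Normal, min: 135.0, max: 145.0}, {name: High, min: 145.0}]
    gradient_delta: 5.0
    stable_hours: 36.0
  - name: wbc
    source: lab
    unit: 10^9/L
    itemid: 50012
    states: [{name: Low, max: 4.5}, {name: Normal, min: 4.5, max: 10.0}, {name: High, min: 10.0}]
    gradient_delta: 1.0
    stable_hours: 36.0
  - name: body_temperature
    source: chart
    unit: degC
    itemid: 20001
    states: [{name: Hypothermia, max: 36.2}, {name: Normal, min: 36.2, max: 37.2}, {name: Fever, min: 37.2}]
    gradient_delta: 0.5
    stable_hours: 2.0
  - name: glasgow_coma_scale
    source: chart
    unit: points
    itemid: 20002
    # GCS is integer-valued and lower-is-worse; the 8-12 normal band maps to the
    # Moderate state, with the upper cutoff at 13 so the integer 12 stays Moderate.
    states: [{name: Severe, max: 8.0}, {name: Moderate, min: 8.0, max: 13.0}, {name: Mild, min: 13.0}]
    gradient_delta: 2.0
    stable_hours: 2.0
  - name: mean_pressure
    source: chart
    unit: mm Hg
    itemid: 20003
    states: [{name: Low, max: 65.0}, {name: Normal, min: 65.0, max: 80.0}, {name: High, min: 80.0}]
    gradient_delta: 5.0
    stable_hours: 1.0
  - name: heart_rate
    source: chart
    unit: bpm
    itemid: 20004
    states: [{name: Bradycardia, max: 60.0}, {name: Normal, min: 60.0, max: 80.0}, {name: Tachycardia, min: 80.0}]
    gradient_delta: 10.0
    stable_hours: 1.0
  - name: respiratory_rate
    source: chart
    unit: breath/min
    itemid: 20005
    states: [{name: Low, max: 7.0}, {name: Normal, min: 7.0, max: 14.0}, {name: High, min: 14.0}]
    gradient_delta: 3.0
    stable_hours: 1.0
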