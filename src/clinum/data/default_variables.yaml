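# Default variable specifications.
#
# Term lists are shipped verbatim from the published dictionary (including
# apparent typos such as "tear" under temperature and "tachypea" under
# respiratory rate); remove or extend them via a user config.
#
# viable_range entries marked "[invented default]" have no published source
# and exist only so the pipeline is runnable out of the box; override them
# for real use.  All ranges are inclusive at both ends.

temperature:
  terms: [t, fever, t-max, fevers, ta, te, tmax, tear, temp, tm, tmp, tmt,
          tp, tpr, tr, tre, tt, temperature, afebrile]
  viable_range: [93, 110]          # degrees Fahrenheit
  formats: [integer, decimal]
  condition_policy: reject_conditions
  unit: "°F"
  group_eligible: true

blood_pressure:
  terms: [b/p, bps, bp, blood pressure, hypertensive, hypotensive]
  viable_range: [40, 300]          # systolic, mmHg [invented default]
  secondary_range: [20, 200]       # diastolic, mmHg [invented default]
  formats: [fraction]
  condition_policy: reject_conditions
  unit: mmHg
  group_eligible: true

respiratory_rate:
  terms: [rr, rp, r, resp., respiratory, respiration, respirations,
          tachypea, breathing]
  viable_range: [4, 60]            # breaths/min [invented default]
  formats: [integer, decimal]
  condition_policy: reject_conditions
  unit: breaths/min
  group_eligible: true

heart_rate:
  terms: [hr, hrt, p, afib, af, tach, nsr, tachy, pulse, pulses,
          tachycardia, tachycardic, bradycardic, sinus]
  viable_range: [20, 300]          # bpm [invented default]
  formats: [integer, decimal]
  condition_policy: reject_conditions
  unit: bpm
  group_eligible: true

o2_saturation:
  terms: [sat, sats, sating, satting, desat, o2sat, o2sats, pox, spo2, sa,
          sao2, s, oximetry, o2, saturation, saturating, saturations,
          desaturation, desaturations, desaturates, desaturate, desaturated]
  viable_range: [50, 100]          # percent [invented default]
  formats: [integer, decimal, percent]
  condition_policy: reject_conditions
  unit: "%"
  group_eligible: true

ejection_fraction:
  terms: [ef, ejection fraction, lvef]
  viable_range: [0, 100]           # percent; decimals <= 1.0 rescaled x100
  formats: [integer, decimal, percent, range]
  condition_policy: accept_conditions
  unit: "%"
  group_eligible: false

hba1c:
  terms: [glycated haemoglobin, glycated hemoglobins, glycated hemoglobin,
          glycohemoglobin a, glycosylate haemoglobin, glycosylate hemoglobin,
          glycosylated haemoglobin a, glycosylated haemoglobin,
          glycosylated hb, glycosylated hemoglobin a,
          glycosylated hemoglobins, glycosylated hemoglobin,
          haemoglobin a1c, hb a1a + b, hb a1c, hb a1, hba1c, hba1,
          hemoglobin a1c, hemoglobin glycated, a1c, a1cs, hgba1c, hb1c,
          hga1c]
  viable_range: [0, 30]            # percent
  formats: [integer, decimal, percent]
  condition_policy: accept_conditions
  unit: "%"
  group_eligible: false

creatinine:
  terms: [creat, crn, cr, creatinine, scr, cri, creatinin, ctn, cre, crea]
  viable_range: [0, 50]            # mg/dL
  formats: [integer, decimal]
  condition_policy: reject_conditions
  unit: mg/dL
  group_eligible: false

height:
  terms: [h, hgt, hh, ht., height]
  viable_range: [36, 90]           # inches [invented default, unvalidated]
  formats: [integer, decimal]
  condition_policy: reject_conditions
  unit: in
  group_eligible: false

weight:
  terms: [wt, w, wgt, wi, bw, weight]
  viable_range: [2, 500]           # kg or lb [invented default, unvalidated]
  formats: [integer, decimal]
  condition_policy: reject_conditions
  unit: kg
  group_eligible: false
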