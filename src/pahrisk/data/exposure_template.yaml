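# Exposure-factor template for the intake cancer-risk model.
#
# Every factor accepts either a point value or a distribution spec:
#   dr: 5.0
#   dr: {family: lognormal, mean: 5.0, sd: 2.0}              # arithmetic moments
#   bw: {family: normal, mean: 60, sd: 10, truncation: [30, 120]}
#   ed: {family: triangular, low: 5, mode: 30, high: 50}
#   ef: {family: uniform, low: 180, high: 365}
#
# Units — supply values consistent with YOUR TEQ scale:
#   dr   daily herbal intake, g/day
#   csf  cancer slope factor, (mg/kg.day)^-1
#   ef   exposure frequency, days/year (<= 366)
#   ed   exposure duration, years
#   bw   body weight, kg
#   at   averaging time, days
#
# NOTE ON UNITS: the TEQ operation returns sum(C_i * TEF_i) / scale_divisor
# with C_i in ug/kg and a default divisor of 1000, i.e. BaP-equivalents in
# mg/kg.  With dr in g/day the product TEQ*dr is then in ug/day; divide-and-
# conquer your CSF units accordingly (or change scale_divisor in a TEF
# config).  The pipeline performs no implicit unit conversion: the numbers
# below are a documented template, not study estimates, and must be replaced
# for real analyses.
groups:
  - group: adult
    dr: 5.0
    csf: 7.3
    ef: 365
    ed: 30
    bw: 60
    at: 25550
  - group: child
    dr: 2.0
    csf: 7.3
    ef: 365
    ed: 10
    bw: 25
    at: 25550
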