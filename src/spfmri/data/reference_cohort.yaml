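# Reference per-group parameter distributions used to calibrate the
# synthetic two-group (low/high grade) cohort generator.  Each cell gives
# the group median and interquartile range (q1-q3) of a published tumor-grading
# cohort on the conventional reporting scale:
#   ADC_0_1000, D, D_star : x10^-3 mm^2/s
#   SPF, f                : percent
#   Ktrans                : 1/min
#   v_e, v_p              : fraction
group_sizes:
  low: 19
  high: 31
parameters:
  ADC_0_1000:
    low:  {median: 1.26, q1: 1.07, q3: 1.34}
    high: {median: 1.03, q1: 0.79, q3: 1.13}
  SPF:
    low:  {median: 10.47, q1: 7.71, q3: 14.23}
    high: {median: 23.56, q1: 21.73, q3: 31.49}
  f:
    low:  {median: 4.05, q1: 3.08, q3: 5.80}
    high: {median: 9.22, q1: 6.83, q3: 14.41}
  D:
    low:  {median: 1.22, q1: 1.03, q3: 1.28}
    high: {median: 1.02, q1: 0.77, q3: 1.11}
  D_star:
    low:  {median: 7.88, q1: 4.95, q3: 10.32}
    high: {median: 12.69, q1: 12.09, q3: 14.77}
  Ktrans:
    low:  {median: 0.041, q1: 0.018, q3: 0.058}
    high: {median: 0.140, q1: 0.076, q3: 0.192}
  v_e:
    low:  {median: 0.132, q1: 0.023, q3: 0.228}
    high: {median: 0.204, q1: 0.165, q3: 0.559}
  v_p:
    low:  {median: 0.029, q1: 0.020, q3: 0.058}
    high: {median: 0.055, q1: 0.033, q3: 0.076}
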