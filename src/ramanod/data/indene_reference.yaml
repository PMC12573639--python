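# Reference Raman shifts of indene (cm^-1) used for wavenumber calibration.
# Pair these with the measured pixel positions of the corresponding peaks
# in your indene spectrum to build the (pixel, wavenumber) table consumed
# by ramanod.preprocess.calibrate_wavenumber.
indene_shifts_cm1:
  - 730.4
  - 1018.3
  - 1205.6
  - 1552.7
  - 1610.2
  - 2892.2
  - 3054.7
polynomial_degree: 3
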