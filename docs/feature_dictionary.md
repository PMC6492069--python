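# Feature dictionary

130 predictor columns per patient-day: 13 basic features plus, for each, trailing-window statistics over 3, 6 and 12 days (mean, sample SD with denominator w-1, and the OLS gradient of value against day index, units per day).

## Basic features

- `steps_during_bedtime` — steps (sum over the 8-h night window)
- `steps_during_daytime` — steps (sum over sunrise..sunset)
- `light_exposure_during_bedtime` — lux (mean over the 8-h night window)
- `light_exposure_during_daytime` — lux (mean over sunrise..sunset)
- `sleep_length` — hours (offset - onset)
- `sleep_efficiency` — percent, tracker-reported
- `sleep_onset_dev` — hours; circular deviation from trailing 7-day circular-mean onset
- `sleep_offset_dev` — hours; circular deviation from trailing 7-day circular-mean offset
- `HR_CR_amplitude` — bpm; cosinor amplitude of the trailing 48-h HR window
- `HR_CR_acrophase` — hours-of-day in [0,24); clock time of the cosinor peak
- `HR_CR_mesor` — bpm; cosinor rhythm-adjusted mean
- `HR_CR_rsquared` — fraction in [0,1]; cosinor goodness of fit
- `resting_heart_rate` — bpm; minimum of the 5-min rolling-mean HR of the day

## Extended features

For every basic feature `F`, window `w` in {3, 6, 12} days and statistic `s` in {mean, stdev, gradient}: `F_<w>d_<s>` computed over days d-w+1..d; missing if any constituent day is missing. `HR_CR_acrophase` windows are unwrapped (shortest-arc continuation) before SD/gradient; the windowed mean is re-wrapped into [0, 24).
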