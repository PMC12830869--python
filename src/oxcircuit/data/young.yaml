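# Young (3-month) rat spinotrapezius cohort: means with CI95 half-widths.
label: young
n_animals: 11      # arterial blood PO2 sample size
n_profiles: 117    # interstitial PO2 profile count
Pa: 91.9
Pa_ci95: 5.4
Pr: 66.7
Pr_ci95: 2.5
Pw: 42.5
Pw_ci95: 2.6
tau_w: 9.0
tau_w_ci95: 0.7
tau_r: 15.4
tau_r_ci95: 0.7
noise_sd: 1.0
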