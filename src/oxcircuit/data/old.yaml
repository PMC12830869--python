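# Old (23-month) rat spinotrapezius cohort: means with CI95 half-widths.
label: old
n_animals: 12      # arterial blood PO2 sample size
n_profiles: 139    # interstitial PO2 profile count
Pa: 81.3
Pa_ci95: 5.1
Pr: 60.2
Pr_ci95: 2.2
Pw: 28.3
Pw_ci95: 2.8
tau_w: 15.9
tau_w_ci95: 0.6
tau_r: 41.4
tau_r_ci95: 1.4
noise_sd: 1.0
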