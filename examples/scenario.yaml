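# Example kinpref scenario file.
#
# Any subset of Scenario fields may be given; omitted fields keep the
# study-design defaults (24 families, 96 choice trials with 7 breach flags,
# 12 mixed-sex + 12 same-sex arenas of 8 fish, 30-min recordings).
# Mapping fields (behavior_* below) are merged key-by-key into the defaults.

# --- dichotomous choice trials -------------------------------------------
exp1_trial_duration_s: 1800.0   # 30-min choice period
exp1_frame_rate: 10.0           # tracker frames per second
p_zone_female: 0.68             # stationary probability of being in either zone
p_zone_male: 0.58
bias_b: 0.5                     # related-zone share of zone time; 0.5 = no kin bias
sop_slope_body_length: 0.05     # SOP units per mm of (related - unrelated) length
latent_pref_sd: 0.0             # per-individual kin preference shared across designs

# --- free-swimming arenas -------------------------------------------------
n_arenas: 12
arena_duration_s: 1800.0
arena_radius_cm: 18.0           # 36 cm diameter cylinder
heading_persistence: 0.8        # correlated-random-walk autocorrelation, 0..1
attraction_gain: 0.1            # overall social-pull strength
base_attraction: 1.0            # pairwise attraction weight baseline
attraction_virgin_virgin: -0.5  # weight adjustment when both members are virgin
attraction_male_male: -0.6      # ... both male
attraction_related: 0.0         # kin bonus; 0 = no kin structure

# --- association threshold ------------------------------------------------
mean_body_length_cm: 1.76
threshold_multiplier: 2.0       # association radius = 2 body lengths = 3.52 cm

# --- behaviour counts -----------------------------------------------------
behavior_base_rates:            # expected events per arena x status x relatedness cell
  gliding: 2.0
behavior_status_effects:        # log rate ratios, virgin vs experienced
  gliding: 1.33
behavior_relatedness_effects:   # log rate ratios, unrelated vs related
  gliding: 0.0
behavior_dispersion: 2.0        # NB size parameter (variance = mu + mu^2/size)
behavior_arena_sd: 0.3          # SD of the arena random intercept, log scale
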