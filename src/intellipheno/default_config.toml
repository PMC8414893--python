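# Default cohort design and per-genotype behavioral parameters for the
# synthetic event-log generator.  These calibration constants are the one
# place the genotype effect sizes live; code never hard-wires them.
#
# Direction of the built-in genotype contrasts (TG = triple-transgenic AD
# model, NonTg = background-strain control):
#   * TG visit less on the first (novel) day         -> lower visit rates
#   * TG visit corners mostly to drink, not explore  -> lower w_explore
#   * TG more often never learn to drink             -> higher p_drink_fail
#   * TG attend the SRT cue less often               -> lower p_attend
#   * TG suppress the punished corner less           -> lower avoid_learn

[cohort]
n_nontg_per_cage = 8
n_tg_per_cage = 8
n_cages = 1
seed = 0

[schedule]
t_start = 0.0

[params.NonTg]
visit_rate_dark = 5.0      # visits/hour, lights off (20:00-06:00)
visit_rate_light = 1.5     # visits/hour, lights on
w_explore = 0.60           # probability a visit is exploratory vs water-seeking
learning_rate = 0.15       # corner-preference reinforcement per rewarded drink
p_drink_fail = 0.13        # probability the animal never learns to drink
licks_per_bout_mean = 25.0 # mean licks per drinking bout
p_attend = 0.70            # probability of responding during the SRT cue
p_impulsive = 0.15         # probability of a premature poke per SRT trial
rt_scale = 2.0             # latency scale (s) of cue responses
avoid_learn = 0.50         # per-airpuff multiplicative suppression of return

[params.TG]
visit_rate_dark = 4.0
visit_rate_light = 1.2
w_explore = 0.35
learning_rate = 0.15
p_drink_fail = 0.43
licks_per_bout_mean = 25.0
p_attend = 0.55
p_impulsive = 0.15
rt_scale = 2.0
avoid_learn = 0.25

[behavior]
# shared constants, identical for both genotypes
novelty_boost = 0.8           # extra fractional visit rate at introduction, decaying over ~1 day
explore_poke_prob = 0.5       # exploratory visits that include a nosepoke
explore_drink_prob = 0.2      # exploratory visits that drink when the door opens
extinction_rate = 0.10        # per unrewarded poke, multiplicative corner-weight decay
visit_duration_median_s = 20.0
visit_duration_sigma = 0.8    # log-normal sigma of visit durations
lick_interval_s = 0.15        # spacing of lick contacts within a bout
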