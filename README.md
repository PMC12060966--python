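# banditexplore

Analysis toolkit for explore/exploit behavior on a restless three-armed
bandit task. The package covers the full computational pipeline of a
two-group (clinical vs. control style) behavioral study:

- **`task_env`** — constrained random-walk reward contingencies
  (10% chance per trial of a ±0.1 step per arm, bounds [0.1, 0.9],
  rejection-sampled so per-arm and grand time-means stay at 50% ± 2%),
  plus the 25-trial practice gate (≥ 11 points and ≥ 2 switches).
- **`agents`** — generative choice models: a Bayesian learner
  (Kalman-filter value updates, uncertainty bonus φ, perseveration ω,
  softmax inverse temperature β), an RL + choice-kernel learner (RLCK),
  a dual-state RLCK whose learning rate is rescaled on exploit-labeled
  trials, and a uniform-random reference agent.
- **`model_fitting`** — compiled likelihoods, multi-start maximum-likelihood
  fitting, and AIC-weight model comparison.
- **`hmm_explore`** — a structurally constrained 4-state explore/exploit
  HMM (tied transitions, fixed emissions, forced initial explore state)
  fit by Baum-Welch; posterior decoding, strategy metrics, and the
  Boltzmann/Arrhenius energy-landscape summary of the fitted chain.
- **`switch_dynamics`** — inter-switch run lengths and EM for mixtures of
  1–4 geometric distributions with an explicit elbow selection rule.
- **`behavior_metrics`** — model-free session metrics (reward vs. chance,
  optimal choice, the switch family, reward sensitivity).
- **`cohort_analysis`** — z-scored five-feature PCA with permutation tests
  on loadings, Ward clustering with silhouette / Calinski-Harabasz /
  Davies-Bouldin over k = 2..6, two-way consistency ICC, and adjusted
  Pearson residuals.
- **`synthetic_cohort` / `io` / `pipeline` / `cli`** — a synthetic cohort
  generator (no participant data ship with this package), tidy CSV I/O,
  and the end-to-end pipeline.

## CLI

```sh
banditexplore simulate --out cohort/ --seed 1        # synthetic cohort
banditexplore metrics cohort/trials.csv --out metrics.csv
banditexplore fit-hmm cohort/trials.csv --out hmm.csv --labels-out labeled.csv
banditexplore mixture cohort/trials.csv --out mixture.csv
banditexplore fit cohort/trials.csv --model kalman --model rlck --out fits.csv
banditexplore compare fits.csv --out comparison.csv
banditexplore pca features.csv --out pca.json
banditexplore cluster features.csv --out clusters.json
banditexplore report cohort/trials.csv --cognitive cohort/cognitive.csv --out report/
```

Trial CSVs are tidy: `participant_id, session, trial, choice (1–3),
reward (0/1), p1, p2, p3`. Seeds are recorded in every output.

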