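# Methods

## Model and protocol

The stage game is the binary-contribution N-person public goods game:
contribute c = 1 or nothing; the pot is multiplied by b = αN and split
equally, so a focal payoff is r_i = −g_i + α Σ_j g_j with α the marginal
per capita return (MPCR).  Continuous contribution levels are not
supported.  The dilemma range is 1/N < α < 1; configurations outside it
are legal but flagged (`GameConfig.is_dilemma`).

A *group* is N co-learning agents.  The protocol is 30 games × 20
periods; agents learn in **every** period of every game, and the first 10
games (200 periods) are excluded from analysis only, as the learning
phase.  All agents act simultaneously.  The state an agent sees is
{previous own action, previous cooperation fraction of the other N − 1
agents} — nothing else (no payoff feedback, no period index).  At the
start of each game there is no previous round; each agent's fictitious
previous action is drawn uniformly at random and the observed fraction is
computed from those draws, which is an unbiased initial condition.
Cooperation statistics are the retained-window mean per group, then mean
and sample (n−1) standard deviation across 30–50 independent replicate
groups.

Exploration is ε-greedy with ε(t) = 0.001 + 0.25/(1 + t), where t counts
*games* (constant within a game): 0.251 in game 0 decaying to ~0.001.
The printed form of this schedule is typographically ambiguous in the
source material; the floor-plus-hyperbolic-decay reading is the only one
that yields a probability and matches the described behaviour (mostly
random early, almost purely greedy from mid-session on).  Greedy ties are
broken uniformly at random — near-ties are exactly the regime that
matters here, and a systematic tie rule would bias it.

γ is read as the continuation probability of the repeated game
(expected length 1/(1−γ); 10 periods at the default γ = 0.9).
Consequently the TD target bootstraps through the final period of each
game rather than treating it as terminal; terminal masking is available
as a configuration switch (`terminal_bootstrap=False`) but is not the
model.

## Value functions

Each agent owns an independent value function; there is no parameter or
gradient sharing.  Internally a whole group's parameters are stacked
along a leading agent axis so a period costs a handful of batched
matmuls, which is what makes the N = 100 protocol run in seconds; the
stacking is purely an implementation layout and is covered by a test
asserting gradient isolation between agents.

**Tabular.**  The observation grid is exact: {0,1} × {k/(N−1)}.  Updates
are the Watkins stochastic fixed-point iteration Q ← Q + η(y − Q).  η is
either fixed or, for convergence runs, the per-cell decaying step
η = c/(c + visits) with c = 50 (Robbins–Monro; c trades early plasticity
against late averaging, and 50 reaches the 0.02 band within 2×10⁵ updates
in the convergence benchmark).

**Neural.**  Per agent: 2 inputs (action as 0/1, fraction as a real) →
two ReLU hidden layers of 16 units → 2 linear outputs (QD, QC); He
initialization; squared error on the taken action against a frozen
one-step target; one Adam step (β₁ = 0.9, β₂ = 0.999) per period with
learning rate 0.01, online (batch 1).  A small replay buffer
(`update_mode="replay"`) and a periodically synced target network
(`target_sync`) exist as options but are off by default: the state space
is tiny and the plain online rule *is* the learner whose bounded accuracy
the analysis is about.  Divergence (non-finite loss or parameters)
raises a named error, and a diverged group is recorded as failed with
diagnostics rather than dropped.

The hyperparameters of the original learner were tuned by an external
optimizer per condition and never reported, so the defaults here are the
package's own: the smallest configuration that cleanly separates the easy
and hard regimes.  The learning rate matters most.  Each agent gets only
600 gradient steps per session, and Adam moves each parameter by at most
≈ lr per step, so the reachable output scale in a session is roughly
600 · lr · (depth factor).  At 10⁻³ that is too small even for the
easy-regime value scale (QD = 1 at N = 2, α = 0.2) and agents stay
near-random everywhere; at 10⁻² the easy regime is learned reliably
within a session while the hard-regime scale (QD ≈ 38 at N = 16, α = 0.5,
γ = 0.9, and ≈ 250 at N = 100) remains far out of reach, which is the
intended bounded-accuracy behaviour.  Much larger rates destabilize the
easy regime.  0.01 is therefore the default; all of this is overridable.

## Closed-form oracle

With opponents cooperating i.i.d. with probability ½, expected gains are
r_D = α(N−1)/2 and r_C = r_D − (1−α); neither rewards nor transitions
depend on the observation, so the optimal values are state-independent:
QD = r_D/(1−γ), QC = r_C + γQD for α < 1 (the greedy branch flips for
α ≥ 1, reported with a warning).  The difficulty statistic is
1 − QC/QD = 2(1−α)(1−γ)/(α(N−1)), positive and strictly decreasing in
each of N, α, γ on the dilemma range and vanishing as N → ∞.

Before being trusted as a test oracle the closed form is validated two
ways: a value-iteration solver on the full observation grid with the
exact binomial kernel (`value_iteration_q`, agreement ≤ 10⁻¹⁰) and a
deliberately naive dictionary-and-loops dynamic program living in the
test suite that shares no code with the package.  Note one boundary
case: at N = 8, α = 0.9, γ = 0.9 this derivation gives difficulty
≈ 0.003, although ≈ 0.01 is sometimes quoted for it alongside the
N = 20, α = 0.5 case; we report our computed value.  Closed-form
analysis is only claimed for randomizing opponents — analytic Q-values
under mutual learning are an open problem and not attempted.

## Randomness and reproducibility

Per-group seeds are derived counter-style,
`SeedSequence(master_seed, spawn_key=(cell, group))`, so adding groups or
sweep cells never perturbs earlier random streams.  Tabular runs are
bit-for-bit reproducible from (config, master seed); neural runs are
reproducible per seed.  Each run directory carries a metadata sidecar
with the full configuration and library versions.  A resource guard
refuses sweep cells with N × n_groups above a configurable budget
(default 10 000, the largest product the full protocol ever used) unless
forced.

## Problem sizes used in the checks

The full study summarized 50 groups per condition with per-condition
tuned networks.  The packaged checks run the identical protocol at
reduced replicate counts, chosen as the smallest that keep the
across-group standard error a few percentage points: the group-size trend
(α = 0.5, N ∈ {2, 8, 16}) pools 5 master seeds × 5 groups; the
threshold condition N = 16 uses 10–15 groups; the large-group ceiling
N = 100 uses 10 groups.  The tabular convergence benchmark runs a single
learner for 2×10⁵ updates against coin-flip opponents and requires
agreement with the closed form within 0.02.

## What the synthetic conditions do and do not show

All inputs are configuration; there is no external data.  Forced-policy
agents (all-C, all-D, forced-random) provide exact and binomial fixtures
for the pipeline.  The random-opponent environment used by the oracle
checks removes co-adaptation by construction, which is what makes it
solvable — passing it shows the learning rule is correct, not that
co-learning dynamics are fully characterized.  The co-learning
simulations show the qualitative mechanism (cooperation rising with N
and α, saturating near one half); exact cooperation levels depend on the
network capacity, learning rate and training length, as the difficulty
analysis itself predicts, and are not portable to humans, who face
social norms, framing and continuous contribution choices absent from
this model.

## Known limitations

- No spatial or network structure, punishment/reward institutions,
  heterogeneous endowments, or continuous contributions.
- Neural defaults are deliberately small; markedly different
  architectures may shift the cooperation plateau, though not the
  direction of the trends.
- Payoffs and value updates are computed in double precision; only the
  observation grid k/(N−1) is treated as exact (reconstruction of k is
  validated and lossless).
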