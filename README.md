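# tubetest

Analysis of social dominance hierarchies measured with the tube test in
group-housed rats, built around the two-phase design used to study a
fragile-X (*Fmr1* knockout) rat model: does losing FMRP change an
animal's ability to form and hold a rank, and how does the experience
of winning or losing shape later contests with strangers?

In the tube test two rats meet head-on in a tube; the one that forces
or induces the other to retreat wins.  A study population of 56 rats
lives four to a cage — 3 wild-type (WT) cages, 4 knockout (KO) cages
and 7 mixed cages of 2 WT + 2 KO.  In **phase I** every within-cage
pair (6 pairs) runs a 5-trial block per session for 10 sessions; the
majority winner of a block is the contest winner, each trial win is
worth 2 points, and session points order the four cage-mates into ranks
1–4 (ties broken by the tied pair's own head-to-head block).  In
**phase II** whole cages meet in round-robin tournaments: 16 cross-cage
pairs, 5 trials per pair, repeated over 3 sessions.

The package provides:

* `contest_io` — a long-format trial-record model, a documented CSV
  dialect with lossless round trip, and experimental-design validation;
* `ranking` — block scoring, point tallies, within-cage ranks with the
  deterministic tie-break policy, and per-rat rank trajectories;
* `metrics` — the rank-variability measures: **normalized variance**
  (sample variance of the rank sequence as % of the attainable maximum,
  which is 2.5 for 10 sessions of ranks 1–4) and **stability** (% of
  consecutive-session transitions with rank retained, 9 transitions =
  100%), each also split into sessions 1–5 vs 6–10, plus the
  hyper-stable / hyper-unstable subgrouping;
* `stats` — the inferential conventions: uncorrected one-degree-of-
  freedom χ² of win counts against an even split, pooled-variance
  Student *t* (df = n₁+n₂−2), Pearson *r* with regression slope;
* `tournaments` — phase-II cross-tabulations by genotype (with
  cage-type filters) and by phase-I rank class (ranks 1–2 = high,
  3–4 = low; the informative contrast uses only high-vs-low contests,
  8 of the 16 pairs per tournament);
* `simulate` — a seeded latent-strength contest generator
  (Bradley–Terry-style logistic win probabilities, winner/loser
  strength updates, per-animal day-to-day volatility, and a knockout
  lock-in mechanism producing bimodal stability) so the whole pipeline
  is testable without any animal data;
* `pipeline` / `cli` — orchestration of simulate → validate → rank →
  metrics → stats → tournaments with CSV outputs and a provenance
  header, behind the `tubetest` command.

## Worked example

```python
import tubetest as tt
from tubetest.pipeline import run_phase1_analysis, run_phase2_analysis

sim = tt.simulate_study(tt.default_paper_scenario(seed=11))
p1 = run_phase1_analysis(sim.records, sim.roster)

chi = p1.contrasts["mixed_genotype_wins"]
print(f"mixed-cage wins  WT {chi.wins_a} : KO {chi.wins_b}  "
      f"chi2(1) = {chi.chi2:.2f}, p = {chi.p:.2g}")

t = p1.contrasts["single_variance_t"]
print(f"single-line variance  WT {t.mean_a:.1f}% vs KO {t.mean_b:.1f}%  "
      f"t({t.df}) = {t.t:.2f}, p = {t.p:.2g}")

p2 = run_phase2_analysis(sim.records, sim.roster, p1)
hl = p2.rank_class_tabs.high_vs_low
print(f"phase II high vs low  {hl.wins['high']} : {hl.wins['low']}  "
      f"chi2(1) = {hl.chi2.chi2:.1f}, p = {hl.chi2.p:.2g}")
```

prints

```
mixed-cage wins  WT 180 : KO 100  chi2(1) = 22.86, p = 1.7e-06
single-line variance  WT 4.8% vs KO 31.9%  t(26) = -3.71, p = 0.001
phase II high vs low  117 : 27  chi2(1) = 56.2, p = 6.4e-14
```

Reading: in mixed cages wild-types won 180 of 280 cross-genotype
contests — the knockout subordination phenotype; knockout rank variance
in single-line cages is several times the wild-type level; and in
phase-II tournaments a rat's phase-I rank class, regardless of
genotype, predicts contests against strangers — the experience
(winner/loser) effect.  The same run from a shell:

```sh
tubetest reproduce-paper --seed 11 --out out/
```

```
seed=11  phase-I records=4200
  WT wins more mixed-cage contests: reproduced
  KO rank variance higher (single-line cages): reproduced
  WT split-half stability correlated: reproduced
  KO stability bimodal (mixed cages): reproduced
```

with full tables (rankings, per-rat metrics, contrasts, correlations,
tournament cross-tabs, provenance) written to `out/`.

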