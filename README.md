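# kintag

Deterministic and agent-based simulation of **genetic kin recognition
under host–parasite coevolution** in a four-locus haploid population.

Individuals carry two candidate recognition tag loci — `Resist` (also
determines parasite susceptibility, up to `L_max` alleles) and `Neutral`
(no role outside recognition) — plus a two-allele `Choice` locus selecting
which tag locus is consulted when assessing partners, and a two-allele
`Trait` locus (conditional helping vs defection). Each generation:

1. **Social encounters** in a viscous population (clone with probability
   `theta`, nonrelative otherwise); tag mismatch triggers reassociation
   with probability `alpha`. The per-generation match probability for a
   tag at frequency `X` is `(theta + (1-theta)X) / (1 - alpha(1-X)(1-theta))`.
2. **Social interactions**: matched helpers pay fecundity cost `c` and
   their partner receives benefit `b`.
3. **Parasite selection**: fecundity loss `d * Z`, where `Z` is the
   population frequency of the individual's `Resist` allele recorded
   `lag` generations ago (lagged negative frequency dependence).
4. Selection on the product of the two payoffs, then free recombination
   between all four loci, then symmetric mutation at `Trait`/`Choice`.

This reproduces, at desk scale: positive frequency dependence eroding tag
diversity (Crozier's paradox), its rescue by rapidly adapting parasites,
the parasite-susceptibility cost of recognizing kin on a resistance
locus, selection of the recognition locus toward the most diverse tag
locus, and the build-up of diversity at the otherwise-neutral locus by
genetic hitchhiking when the recognition locus can evolve.

## Layout

| module | contents |
|---|---|
| `kintag.genotype_core` | parameters, genotype space, population state, free recombination (16-mask decomposition + brute-force oracle), mutation |
| `kintag.social_payoffs` | match probability, per-genotype social payoffs (exact help-budget conservation), tag relatedness `R_tag`, Hamilton check |
| `kintag.parasite_dynamics` | lagged `Resist` frequencies, fecundity multipliers, susceptibility |
| `kintag.observables` | tag diversity (gene-diversity and effective-tags scalings), tag–trait linkage disequilibrium, per-generation snapshots |
| `kintag.equilibrium_runner` | lifecycle step, fixed-point / limit-cycle iteration, parameter sweeps, figure presets |
| `kintag.montecarlo_oracle` | finite-N agent-based realization of the same lifecycle (validation oracle) |
| `kintag.cli_io` | YAML config, CSV/JSONL/JSON serialization, `kintag` CLI |

## CLI

```sh
kintag run   --set d=0.5 --set lag=2 --out results/run            # one equilibrium run
kintag sweep --grid lag=0,2,10 --grid d=0.1,0.5,0.9 \
             --set scenario=choice_fixed_resist --set mu_choice=0 \
             --set q0=1.0 --baseline --out results/sweep          # grid + b=c=0 baseline
kintag preset fig3   # lag x d sweep, recognition fixed on Resist
kintag preset fig5b  # evolving vs fixed recognition locus at alpha=0.99
kintag preset fig6   # hitchhiking build-up at one low-lag cell
kintag oracle -n 10000 -g 200 --out results/oracle                # agent-based run
kintag check         # quick invariant battery
```

Presets: `fig1b` (match-probability curve), `fig4b` (relatedness vs tag
frequency), `fig3`, `fig5a`, `fig5b`, `fig6`. Sweep tables are CSV with a
stable schema (`lag, d, alpha, mu_choice, div_resist_scaled,
div_neutral_scaled, div_resist_eff, div_neutral_eff, p_bar, choice_freq,
susceptibility, susceptibility_baseline, ld_assoc_resist,
ld_assoc_neutral, status`); every run writes a JSON metadata sidecar with
the full config and seed, so identical (config, seed) pairs rerun
bit-identically.

Config files are YAML with the same keys as the CLI `--set` flags
(`theta, b, c, d, lag, alpha, L_resist, L_neutral, L_max, mu_trait,
mu_choice, max_generations, fixed_point_tol, cycle_window, seed,
scenario, p0, q0, epsilon, ...`); flags override the file. Scenarios:
`choice_evolving` (default), `choice_fixed_resist` (requires
`mu_choice=0, q0=1`), `choice_fixed_neutral` (`mu_choice=0, q0=0`).

Two diversity scalings are reported side by side: `div_*_scaled` is
max-normalized gene diversity `(1 - sum x^2)/(1 - 1/L_max)` and
`div_*_eff` is the effective-number-of-tags scaling
`(1/sum x^2 - 1)/(L_max - 1)`. Both are 1 at full equifrequent
polymorphism and 0 at monomorphism; the latter is far more sensitive
near monomorphism.

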