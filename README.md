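# standreflex

Neuro-musculoskeletal simulation of perturbed standing balance controlled by
delayed proprioceptive reflexes.

## The problem

How much of human standing balance can spinal reflexes alone explain?
`standreflex` builds a sagittal-plane model of a person standing on a
platform that translates in random square pulses, controls its 18 Hill-type
muscles purely with delayed force feedback (Golgi tendon organs) and length
feedback (muscle spindles), and identifies the controller parameters by
minimizing muscular effort subject to "stay standing" constraints.  The
package is aimed at researchers in computational biomechanics and motor
control who want a fully inspectable, scriptable version of this experiment:
every stage — plant, muscles, reflex controller, perturbation protocol,
optimizer, evaluation — is an importable module with a CSV-level interface.

## The model in brief

* **Plant** — 7 segments (trunk+head, thighs, shanks, feet), 9 DOF floating
  base, revolute hips/knees/ankles, heel+toe spring-damper contact with
  stick-slip friction, platform driven kinematically (its 1000 kg mass makes
  the human's reaction negligible).
* **Muscles** — 9 per leg (all mono- and bi-articular muscle groups of the
  leg), four-element Hill type: CE with force-length and force-velocity,
  SEE with quadratic toe, PE, and a buffer element; first-order activation
  dynamics.
* **Controller** — per muscle `u = clamp(u0 + g_eff * F̂(t−Δt) + g_eff *
  (l̂(t−Δt) − l_off)⁺, 0.001, 1)` with muscle-specific delays (35–100 ms).
  The effective gain g_eff is zero while the whole-body COM lies inside a
  dead zone within the base of support and ramps to ±G outside it
  (equal-and-opposite on the heel/toe sides): control is intermittent.
* **Objective** — minimize `f(z) = (1/T) ∫ Σ a_i(t)² dt` over T = 100 s
  subject to surviving > 100 s, final chest height > 1.3 m and mean ankle
  excursion < 0.05 m, solved by a lexicographic particle swarm optimizer
  (feasibility strictly dominates effort).
* **Evaluation** — Pearson correlation of simulated vs experimental joint
  angles and moments (2nd-order zero-phase Butterworth at 16 Hz on the
  experimental side, linear resampling onto simulation time points).

Three controller architectures are supported: `base` (force + length
feedback), `length_only`, `force_only`.  Published optimized parameter
tables ship as presets (`base`, `length_feedback`, `force_feedback`);
`tuned_*` presets re-optimized for this package's default anthropometry are
what the synthetic-data pipeline uses.

See `docs/methods.md` for assumptions, parameter tables, and limitations.

## Worked example

Simulate 110 s of perturbed standing with the tuned base controller and
score it:

```python
import standreflex as sr

model = sr.build_plant()                    # 80 kg / 1.80 m by default
muscles = sr.default_muscles()
params = sr.load_preset("tuned_base")
signal = sr.generate_signal(seed=1, total_duration=110.0)

result = sr.run_episode(model, muscles, params, sr.Architecture("base"),
                        signal, sr.EpisodeConfig())
ok, vals = sr.constraint_values(result)
print(f"survived {result.survived:.1f} s past onset, effort {result.effort:.3f}")
for name, v in vals.items():
    print(f"  {name}: {v['value']:.3f} (limit {v['limit']}) "
          f"{'ok' if v['ok'] else 'VIOLATED'}")
```

prints

```
survived 108.0 s past onset, effort 2.779
  duration: 108.000 (limit 100.0) ok
  chest_height: 1.659 (limit 1.3) ok
  ankle_excursion: 0.001 (limit 0.05) ok
```

i.e. the controller rides out the full perturbation sequence (the episode
ends at 110 s, 108 s after perturbation onset), ends upright (chest well
above 1.3 m), and its feet stay put on the platform (mean absolute ankle
drift ~1 mm).  The effort value is the time-averaged sum of squared
activations over all 18 muscles.  Standing under this perturbation regime
is a chaotic, barely-stabilized process — survival of any single episode
under a *new* perturbation draw is statistical (the presets ride out
roughly one in two draws in full; see `docs/methods.md`), which mirrors the
original observation that such controllers do not withstand arbitrary
perturbation sequences indefinitely.

The same pipeline from the shell:

```bash
standreflex gen-signal --seed 1 --duration 110 --out signal.csv
standreflex simulate --preset tuned_base --signal signal.csv \
    --out traj.csv --eval-out traj_eval.csv
standreflex synth --preset base --signal-seed 1 --out pseudo_exp.csv
standreflex evaluate --sim traj_eval.csv --exp pseudo_exp.csv
standreflex optimize --arch base --warm-start mystart.csv --out best.csv
```

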