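# nloswitch

Inverse design of nonlinear-optical (NLO) molecular switches by greedy
best-first search over discrete functionalization patterns, with the
hyper-Rayleigh-scattering (HRS) first hyperpolarizability as the
underlying response and switch-contrast figures of merit as the search
target.

The package is written for computational chemists studying switchable
chromophores — hexaphyrin redox switches in particular, whose 26/28/30
π-electron states (**26R**, **28R**, **30R**) turn the second-order NLO
response ON and OFF.  It provides the full design loop around any
property oracle (tabulated βHRS databases or seeded synthetic
landscapes standing in for DFT): pattern spaces, response invariants,
figures of merit, the search itself, substituent attribution, database
statistics and chemical-space maps.

## The model

**Response.**  For a freely tumbling molecule, the HRS response is the
rotational invariant of the first hyperpolarizability tensor β,

    βHRS = sqrt(⟨β²_ZZZ⟩ + ⟨β²_ZXX⟩),

where the brackets are isotropic orientational averages of the squared
laboratory-frame components.  Both averages are evaluated exactly by
contracting β with sixth-order SO(3) moment tensors (no Kleinman
symmetry assumed; a symmetrized path is optional), and a brute-force
Euler-angle quadrature serves as an independent numerical oracle.  A
centrosymmetric state has β ≡ 0 and hence βHRS = 0 exactly.

**Figures of merit.**  Two-state switches are scored by the ratio
βON/βOFF (with the legacy 0.001 a.u. floor when βOFF < 10 a.u.), the
difference βON − βOFF, or the revised contrast

    C = (βON − βOFF)² / (βON + βOFF),

which equals βON for a centrosymmetric OFF state and penalizes leaky
OFF states.  A three-state switch with ON states 26R and 30R sharing
the 28R OFF state is scored by

    F = (C26 + C30) / 2 ÷ max(β26, β30)/min(β26, β30),

the average contrast discounted by the dissimilarity of the two ON
responses.

**Search.**  Best-first search optimizes one site set at a time
(substituting every library fragment, keeping the argmax) and re-sweeps
all sites until a full pass changes nothing.  A multi-start driver
varies start pattern and site sequence, merges everything evaluated
into one database, and reports basin statistics.  Steepest ascent then
rebuilds an optimum from the unsubstituted parent one functionalization
per step, decomposing the improvement into %B, %(B-P) and %(CB)
contributions per substitution.

## Worked example

Replay of the 26R→28R search on the deterministic landscape anchored to
the published build-up contrasts (`examples/04_best_first_search.py`):

```text
optimum: NH_NH_NH2_CN_NH2 (contrast 5.99e+04 a.u.)
converged: True after 2 global iterations, 37 distinct patterns evaluated
  R3,6  -> NH2  contrast  1.95e+04 a.u.
  R1,4  -> NH2  contrast  1.95e+04 a.u.
  Y     -> NH   contrast   2.9e+04 a.u.
  R2,5  -> CN   contrast  5.99e+04 a.u.
multi-start: best NH_NH_NH2_CN_NH2, 100% of runs reached it, 61 patterns in the merged database
```

Starting from `NH_O_NH2_F_OH`, the search installs amino donors on the
R3,6 meso pair, keeps them on R1,4, restores pyrrole (NH) on the Y core
sites, and finally places cyano acceptors on R2,5 — a push–pull pattern
whose contrast of 5.99×10⁴ a.u. is ~30× the unsubstituted parent
(2.09×10³ a.u.).  Only 37 of the 1372 valid patterns were evaluated.

The other scripts in `examples/` walk through pattern spaces (01), HRS
invariants (02), metric comparison on three representative switches
(03), steepest-ascent attribution of the three-state optimum — 80% of
its improvement arrives with the final NO2 pair (05), quartile/heatmap
database analytics (06) and the ECFP + t-SNE chemical-space map (07).

## Layout

| Module | Contents |
| --- | --- |
| `scaffold_space` | scaffolds, site sets, fragment libraries, pattern parsing/enumeration, substituent classification |
| `hrs_response` | β tensors, orientational invariants, quadrature oracle, centrosymmetry threshold |
| `figures_of_merit` | ratio / legacy ratio / difference / revised contrasts, three-state function |
| `property_oracle` | lookup + synthetic oracles, seeded landscapes, published-value fixtures |
| `bfs_optimizer` | site optimization, global-iteration search, multi-start driver |
| `steepest_ascent` | build-up attribution, %B / %(B-P) / %(CB) tables, synergy increments |
| `database_analysis` | quartile groups, core-modification occupancy, EDG×EWG heatmaps, binning |
| `chemspace_map` | structure templates (hexaphyrin macrocycle builder), ECFP fingerprints, t-SNE |
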