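# Methods

## The problem

Serial crystallography merges one still diffraction pattern from each of
thousands of microcrystals.  Each still carries its own scale (crystal
volume, beam intensity), records only partial reflection intensities, and
contributes counting noise; merging relies on the law of large numbers to
converge on true intensities.  Until enough stills have been merged,
model-phased electron-density maps are dominated by the phases — and
therefore by the shape — of the model used to compute them.  Such maps look
deceptively good precisely when the data are worst.

The perturbed-model real-space difference density (PMRDD) test turns this
bias into a measurement.  The phasing model is deliberately damaged in two
ways before map calculation:

1. a core, well-ordered aromatic side chain is **truncated** to an
   alanine-like stub (N, CA, C, O, CB kept);
2. a second core aromatic is **moved to a wrong rotamer** that does not
   clash with the rest of the model.

Data that have genuinely overcome phase bias show positive mFo−DFc density
where the true side chains are, negative density on the wrong rotamer, and
little 2mFo−DFc density left at the wrong position.  Data that have not
reproduce the damaged model instead.

## Pipeline

`run_series` executes, for each rung N of an ascending ladder of crystal
counts:

1. **Simulate** (or load) per-crystal observations.  Per crystal c:
   scale g_c ~ LogNormal(0, σ_g); an observed subset of the symmetry-unique
   reflection set; per observation a partiality p ~ U(p_lo, p_hi) and
   I = g_c·p·I_true + ε with ε ~ N(0, σ²), σ² = σ_read² + α·g_c·p·I_true.
   I_true = |F|² from direct summation over the true model
   (Cromer–Mann form factors, isotropic B).
2. **Resolve indexing ambiguity** (trigonal case): leave-one-out
   correlation clustering against a running merged reference, global flip
   anchored to the phasing model's |Fc|².
3. **Scale**: alternate reference merge / per-crystal least-squares scale
   k_c = Σ I_ref·I_c / Σ I_c², with 4σ outlier rejection (two passes) and
   rejection of crystals with < 10 usable reflections.
4. **Merge**: unweighted mean per canonical reflection (Monte Carlo
   spirit); standard error from the sample spread; odd/even-crystal half
   sets for Rsplit = (1/√2)·Σ|I₁−I₂| / (½·ΣI₁+I₂) and CC1/2.
5. **Maps**: |Fo| = √max(I,0) scaled to |Fc| by a k/B Wilson-style fit
   (log-linear seed + Gauss–Newton polish); per-shell σA =
   clamp(corr(Eo,Ec), 0.05, 0.99), D = σA·√(⟨Fo²⟩/⟨Fc²⟩), per-reflection
   figure of merit m = I₁(X)/I₀(X), X = 2σA·Eo·Ec/(1−σA²) (all reflections
   treated as acentric); coefficients 2m|Fo|−D|Fc| and m|Fo|−D|Fc| with
   calculated phases; unobserved reflections filled with D|Fc| in the
   2mFo−DFc map (the bias mechanism) and zero in the difference map; FFT
   onto a grid with spacing ≤ d_min/3; density normalized to mean 0 /
   r.m.s.d. 1, the contouring unit.
6. **Score** (trilinear interpolation of the normalized maps):
   - `recovery_deleted`: mean mFo−DFc at the deleted atoms' true positions;
   - `recovery_moved`: mean mFo−DFc at the moved side chain's true positions;
   - `displacement_negative`: mean mFo−DFc at the false rotamer atoms;
   - `bias_index`: mean 2mFo−DFc at the false atoms divided by the mean at
     control atoms (side chains of the five best-ranked unperturbed
     aromatics) — ≈1 for a pure Fc map, small once data dominate.
   Scored positions within 1.6 Å of a retained model atom are excluded
   (their density is the stub's, not recovery).
7. **Verdict**: sufficient iff recovery_deleted ≥ 3 AND recovery_moved ≥ 3
   AND displacement_negative ≤ −3 AND bias_index ≤ 0.35.  The ±3 values
   follow the conventional ±3.0 r.m.s.d. difference-map contour; the bias
   threshold is this package's calibration.  The underlying judgement is
   visual in practice and has no canonical numeric form; raw scores are
   always reported so users can apply their own.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `scale_sigma` | 0.4 | lognormal σ of per-crystal scales |
| `partiality_range` | (0.1, 1.0) | uniform partiality per observation |
| `noise_gain` | 1.0 | signal-proportional variance term |
| `noise_floor` | 2% of median I_true | read-noise σ (intensity units) |
| `f_obs` | 0.004 | fraction of unique reflections per still |
| `d_min` | 2.0 Å (CLI) / 1.7 Å (shipped ladder) | resolution limit |
| `min_refl` | 10 | minimum usable reflections per crystal |
| `T_pos`, `T_neg` | 3.0 r.m.s.d. | difference-density thresholds |
| `T_bias` | 0.35 | residual 2mFo−DFc fraction at the false rotamer |

`f_obs` is the one noise knob with no stated value anywhere; it was set so
that the shipped synthetic ladder converges between 10³ and 10⁴ crystals
(verdict at N = 1000 for several seeds) — the regime real serial beamline
ladders occupy — and then frozen.

## The synthetic crystal

`make_test_model` packs 37 ideal-geometry residues (9 aromatics, built
from internal coordinates) into a 28 Å P1 cell with random orientations,
B-factors 10–30 Ų, and ≥ 3.6 Å between residues; the two designated
perturbation targets (a TRP and a TYR) are central, low-B, and kept ≥ 9 Å
apart.  That separation matters: the two targets are sequence-adjacent and
therefore exempt from each other's clash check, and a false rotamer placed
into the deleted side chain's true space would accumulate genuine recovered
density that masquerades as permanent bias.

What the generator does **not** emulate: peptide connectivity and secondary
structure, solvent (bulk or ordered), unit-cell spread across crystals,
Ewald-sphere geometry (the observed subset is Bernoulli-sampled, or slab-
modelled for preferential orientation), anisotropic displacement, and
radiation damage.  A green ladder therefore establishes that the merging
statistics and the bias-to-recovery transition behave correctly under the
stated noise model — not that absolute map quality matches any real
protein crystal.

## Numerical choices

- All Fourier math runs in P1 after symmetry expansion; the point group is
  used only for merging and completeness.  Phases of symmetry mates come
  from the P1-expanded Fc rather than per-operator phase-shift rules.
- Canonical reflection = lexicographic maximum over the orbit (plus
  Friedel mates): total, deterministic, brute-force-testable; systematic
  absences are not filtered (simulated intensities there are ≈ 0).
- The shipped operator table covers P1, P2₁, P2₁2₁2, I222, P3₂21, P6₁22,
  stored as generators and closed (and closure-verified) at load time.
  The P3₂21 indexing-ambiguity operator is (−h,−k,l), the twofold about c
  missing from point group 321.
- F(000) is excluded; maps are mean-zero by construction and normalized to
  r.m.s.d. 1.  A difference map whose raw r.m.s.d. is below 10⁻⁶ of the
  2mFo−DFc map's is reported as exactly flat (normalizing it would only
  amplify floating-point noise).
- Centric reflections get the acentric figure of merit (the tanh branch is
  omitted); the verdict rests on multi-r.m.s.d. density contrasts, not on
  exact weights.
- Scaling convergence: relative k change < 10⁻⁶ or 30 iterations; outlier
  threshold max(4σ_pooled, 10⁻⁸·|I_ref|) so exact data never self-reject.
- Grid guard at 512³ per axis; aliasing guard ensures max index < n/2.

## Known limitations

- No refinement: `r_model` (amplitude residual after k/B scaling) stands in
  for R_work/R_free and is not comparable to refinement R factors.
- Partiality is never modelled during scaling, only simulated; post-
  refinement pipelines would converge at lower multiplicity.
- The bias_index floor is structure-dependent: for this ~300-atom model the
  perturbation is ~6% of the scattering matter, an order of magnitude more
  than for a real protein, so absolute thresholds transfer only
  qualitatively.
- Clash counting ignores symmetry mates and periodic images (the generator
  keeps atoms away from cell walls).
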