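# Methods

`dockprof` post-processes ensemble docking: given an ensemble of receptor
conformations (e.g. MD snapshots), the docked poses of one ligand across
that ensemble, and a partition of the ligand's heavy atoms into named
moieties, it produces a ranked list of candidate *molecular-determinant*
residues — residues whose contacts with the ligand recur across the most
populated pose clusters.

## Pipeline model

1. **Pose distance.** All heavy-atom coordinates of each pose form a point
   set with a fixed correspondence (enforced at load time: every pose of a
   ligand must share element sequence, charges and bond list). Two RMSD
   flavours are offered and the choice is an explicit config field:

   - `superposed` — RMSD after optimal rigid-body superposition
     (SVD/Kabsch with the proper-rotation sign correction). This measures
     *shape* similarity and discards where the pose sits in the pocket.
   - `inplace` — plain coordinate RMSD with no fitting. This measures
     *placement* similarity and is meaningful once all receptor frames
     share one alignment (the `align` stage, a Cα-based rigid fit of every
     frame onto a reference, serves exactly this).

   Which flavour a given upstream clustering tool used is often
   unknowable; both are first-class here and the choice is echoed into
   every output. For docked poses of a small, fairly rigid ligand the
   in-place flavour is usually the informative one: conformers docked into
   distinct sub-sites can be nearly congruent in shape.

2. **Clustering.** Agglomerative clustering with unweighted average
   linkage (UPGMA) on the pose-distance matrix, cut either at a merge
   distance (default 2.0 Å — of the order of the intra-cluster spread a
   useful binding-mode cluster shows) or at a target cluster count.
   Cluster labels are 1-based in descending population order. Equal-merge
   ties are resolved by the linkage implementation's deterministic
   ordering; for continuous RMSD data exact ties have measure zero.

3. **Significant clusters.** A cluster is significant when its population
   strictly exceeds

       threshold = x̄ + 2 δ,

   the mean cluster population plus twice its standard deviation. δ is the
   *sample* SD (n−1 denominator) by default, with a `population` option; a
   single cluster has δ defined as 0 and is never significant. SCP is a
   significant cluster's population, TPSC their total.

   A structural caveat worth knowing: for k clusters the largest
   attainable z-score of one population is (k−1)/√k under the sample
   convention (√(k−1) under population SD), so **no cluster can ever pass
   the threshold when k ≤ 5 (resp. k ≤ 4)**. Real ensemble-docking runs
   produce dozens of clusters and are unaffected, but small synthetic
   systems would always profile nothing. For those the pipeline offers
   `significance: all`, which declares every cluster significant and
   weights FI by plain population share; `threshold` remains the default,
   and the pipeline stops with an explicit error rather than emitting an
   empty profile when the threshold selects nothing.

4. **Contact typing.** Nine contact classes between each pose and its own
   receptor frame, by heavy-atom geometric criteria (hydrogens are not
   required, matching typical docking output):

   | type | criterion (defaults) |
   |---|---|
   | hbond | donor–acceptor heavy atoms ≤ 3.5 Å |
   | ionic | opposite charged-group centroids ≤ 4.0 Å |
   | pi_pi | ring centroids ≤ 5.5 Å; interplanar angle ≤ 30° with lateral offset ≤ 2.0 Å (parallel) or angle ≥ 60° (T-shaped) |
   | pi_cation | cation centre to ring centroid ≤ 6.0 Å, ≤ 30° off the ring normal |
   | hydrophobic | C(only C/S/H neighbours) pair ≤ 4.0 Å, one record per residue |
   | halogen_bond | C–X···A with X···A ≤ 3.5 Å and angle ≥ 140° |
   | water_hbond | a frame water O within 3.5 Å of both a ligand and a residue polar atom |
   | aromatic_hbond | polar atom within 4.0 Å of an aromatic ring carbon (either side) — an operational stand-in for the proprietary definition used by commercial profilers |
   | metal | ligand/protein N/O/S within 2.8 Å of a metal ion |

   Protein chemistry comes from residue-template tables over the 20
   standard amino acids (unknown residues are skipped with a warning);
   ligand chemistry is perceived from elements, bonds, formal charges and
   aromatic flags, with implicit hydrogens inferred from default valences.
   Charged groups pool resonance-equivalent terminal atoms (a sulfate is
   one anionic centre at the centroid of its terminal oxygens). All
   cutoffs are overridable and echoed into the run manifest.

   Records are deduplicated to one per `(pose, residue, moiety, itype)`:
   the downstream frequency counts poses, so several geometric instances
   in one pose must not inflate it. Ring-mediated records carry the
   majority moiety of the ring atoms (ties → lowest atom index).

5. **Frequency profiling.** For each significant cluster c and triple
   t = (residue, moiety, type):

       FIPC(c, t) = (# poses of c exhibiting t) / SCP(c)
       FI(c, t)   = FIPC(c, t) · SCP(c) / TPSC

   The FIPC denominator is the cluster's pose population, not an
   interaction count — "frequency of the interaction per cluster" admits
   no other reading that keeps FIPC in [0, 1]. The printed form of the
   weighting is typographically ambiguous between multiplication and
   division by TPSC; only division is dimensionally sensible (weights sum
   to 1 over significant clusters) and matches the stated intent of
   weighting each cluster by its population share. All frequencies are
   exact rationals internally (`fractions.Fraction`), so Σ SCP/TPSC = 1
   holds exactly and a triple present in every pose of every significant
   cluster totals exactly 1; outputs round to 4 decimals.

   Summing FI over a residue's rows gives the residue ranking; the
   moiety × type breakdown attributes each contact to the part of the
   ligand that makes it.

## Synthetic scenarios

The generator (`dockprof.synthetic`) builds desk-scale stand-ins for an
ensemble-docking campaign, with known ground truth.

- **Toy ligands.** `toy_glucosinolate`: 20 heavy atoms — a three-carbon
  polyol arm ("sugar"), an –O–SO₃⁻ group ("sulfate") and a chlorinated
  benzene arm ("sidechain") — mirroring the moiety anatomy of a
  glucosinolate without its real topology. `toy_dipeptide`: 11 heavy
  atoms, phosphonate + peptide-like core, for two-moiety schemes.
- **Cluster centres.** Centre j applies a fixed recipe: the sulfate and
  side-chain arms swing about the core carbon around different axes
  (changing molecular *shape*), then the whole molecule rotates about an
  anchor oxygen (changing *placement*; the anchor stays put). The recipe
  sequence guarantees pairwise centre separation ≥ 8 Å in place and
  ≥ 1.5 Å superposed for up to 5 centres; the generator verifies both
  against the requested `cluster_sep` and noise level and raises on
  infeasible requests. One C–C bond between swing groups stretches — the
  fixtures are geometric, not physical (no sterics, no force field).
- **Poses.** Each pose is its centre plus isotropic Gaussian noise
  (`noise_sd`, default 0.3 Å) on every heavy atom, shuffled and spread
  round-robin over identical pocket frames so per-frame ranks stay ≤ 10,
  as a docking engine returning 10 poses per run would produce.
- **Planted contacts.** One residue per requested contact, placed from
  idealized side-chain templates so its probe atom satisfies the criterion
  with ≥ 1.0 Å margin (pi stacking at 3.6 Å, metal at 1.8 Å, …), plus a
  matched decoy of the same residue type 0.5 Å *outside* the cutoff. A
  *hub* residue H-bonds the anchor oxygen, which every centre shares, so
  it contacts every cluster and must top the summed-FI ranking. After
  placement the generator re-runs the detector on the noiseless centre
  poses with cutoffs shrunk/grown by 0.25 Å and raises if any planted
  contact is missing or any decoy fires — construction, not calibration.
- **Benchmark.** `standard_scenario_spec()`: k = 3 centres, populations
  200/150/20, noise 0.3 Å, separation 8 Å, 40 frames, all nine contact
  types planted (+hub). `two_cluster_spec()`: 30/5 poses, noise 0.2 Å,
  separation 6 Å. Benchmarks cluster with the in-place metric (the
  planted partition is a placement structure; see §1) and profile with
  `significance: all` (see the k ≤ 5 caveat in §3).
- **Recovery scoring.** Partition agreement is the adjusted Rand index.
  A planted contact or decoy counts as detected when its FIPC reaches 0.5
  in the recovered cluster mapped (by majority) to its target: with
  Gaussian noise a decoy 0.5 Å outside a cutoff flickers into range in a
  few per cent of poses, and frequencies — not single geometric hits — are
  what the method reports. Recall is over planted contacts; precision over
  planted ∪ decoys.

What passing these scenarios does **not** show: robustness to real
conformational flexibility (torsional rather than Gaussian pose
variation), protonation ambiguity, receptor side-chain motion between
frames, or the crowded contact environment of a real binding site. They
validate the bookkeeping — clustering, thresholding, typing, weighting —
on geometry where the right answer is known by construction.

## Numerical choices and degenerate inputs

- Kabsch uses SVD with a sign flip of the smallest singular vector, so the
  result is always a proper rotation; collinear/planar point sets return a
  valid minimum rather than an error. Pairwise matrices use a batched
  3×3-SVD path verified against the per-pair primitive at 1e-9.
- Near-zero RMSDs carry ~1e-7 absolute noise (square root of a cancelled
  sum); tests and consumers should not expect better than 1e-6 there.
- A single cluster: δ := 0, never significant. Empty significant set +
  `threshold` mode: hard error naming the `significance: all` escape.
- Unparseable PDB coordinate fields are a hard error naming file and line;
  alternate locations other than blank/'A' are discarded with a warning;
  waters (HOH/WAT/…) are routed to a separate store and never appear as
  residues.
- Moiety schemes must cover every heavy atom exactly once; 0-based atom
  indices in configs and outputs, verbatim (1-based) PDB residue numbers.

## Limitations

- H-bond detection is distance-only when hydrogens are absent (the common
  docking case); donor/acceptor roles then come from valence heuristics.
- The aromatic-H-bond definition is an open approximation of a proprietary
  one; exact agreement with commercial profilers is not expected.
- No symmetry-equivalent-atom RMSD (e.g. the three equivalent sulfate
  oxygens keep fixed correspondence, matching the upstream tooling's
  behaviour); an automorphism-aware option is future work.
- Only single-model PDB and SDF V2000 are read; no mmCIF/MOL2, no
  protonation assignment, no docking or MD is performed.
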