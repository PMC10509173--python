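# Methods

This note documents the models, numerical choices and limitations of the
package. It covers the generator, the diversity mechanisms, the
pharmacophore score, the kinetics estimators, the structure metrics, and
what the synthetic data do and do not emulate.

## SMILES language model

The Prior/Agent networks are single-layer GRUs (embedding 64, hidden 128 by
default) over a SMILES token vocabulary in which two-letter elements
(`Cl`, `Br`), bracket atoms (`[nH]`, `[N+]`) and ring-closure escapes
(`%nn`) are single tokens. The implementation is plain NumPy (float64) with
analytically derived backpropagation; the gradient of any weighted sum of
sequence log-likelihoods is exposed once and reused for both maximum-
likelihood pre-training (weights −1/N) and the RL loss (see below).
Gradient correctness is asserted against central finite differences in the
test suite. The output layer is initialized to zero, so an untrained model
is exactly uniform over tokens — a convenient analytic baseline.

Training uses Adam (lr 5 × 10⁻³ for pre-training), shuffled mini-batches,
and a 10% held-out split whose per-token NLL is recorded at initialization
and after every epoch. Sampling is ancestral with a hard cap of 140 tokens;
a truncated (non-terminated) sample is passed downstream as-is and almost
always fails to parse, scoring 0 — matching the convention that invalid
SMILES receive zero reward. Sampling never emits the PAD/BEGIN specials
(their probability mass is renormalized away), while reported
log-likelihoods are the raw model log-probabilities of the emitted tokens,
so a sample's log-likelihood equals `sequence_loglik` of the same sequence.

All randomness flows through explicit `numpy.random.Generator` objects;
training and full generation runs are bit-reproducible for a fixed seed on
a given machine.

## Agent update and diversity mechanisms

Each RL step minimizes

    L = mean_i ( log P_prior(A_i) + σ·S_i − log P_agent(A_i) )²

over the sampled batch plus up to 8 sequences replayed from a buffer of the
100 best-scoring sequences seen by that agent (score-descending, canonical
deduplicated). σ defaults to 120 and the total step budget to 10,000, the
published run settings; the desk-scale runs used by the tests and the
acceptance script shrink the budget to 2,000 steps with a 200-step agent
cap, which preserves the refresh arithmetic at 1/5 scale.

The refresh trigger compares the moving average of the last
`averaging_window` (default 100; 50 at desk scale) batch-mean
*tabu-adjusted* scores with the 0.8 threshold, or fires at the step cap.
The window is a design choice — a single-batch spike should not retire an
agent.

Tabu handling:

- scaffolds are atomic Bemis–Murcko frameworks (element and bond orders
  retained, stereochemistry ignored for identity);
- the scaffolds of **all** structures an agent generated are appended at
  refresh (`tabu_source="all"`; `"harvested"` is available);
- an acyclic molecule has the empty scaffold and is never tabu-listed,
  otherwise one acyclic sample would permanently zero all acyclic space;
- zeroing is exact (`== 0.0`) and permanent within a run;
- harvesting ranks by **raw** score but excludes structures whose scaffold
  was already tabu when they were generated: the agent keeps credit for its
  own discoveries while re-discoveries of earlier agents' chemotypes are
  dropped. Both choices are switches on `run_deep_quartet`.

Ties at the harvest boundary break by canonical-SMILES lexicographic order,
making harvests deterministic.

## Pharmacophore model and fit score

Feature kinds: `aromatic`, `hydrophobic`, `cationic`, `hbond_donor`.
Ligand perception: one aromatic feature per aromatic ring at the ring-atom
centroid (ring centroids are also emitted as hydrophobic patches, as
aromatic rings routinely satisfy hydrophobic constraints); cationic
features on nitrogens predicted protonated at pH 7 (aliphatic amines
excluding amides/anilines/imines, ammonium, amidine/guanidine); donors on
N/O bearing ≥ 1 H; hydrophobic features at centroids of connected aliphatic
carbon/halogen groups of ≥ 2 atoms not adjacent to charged atoms. These
rules are declared approximations of a commercial perception engine whose
details are unpublished.

The fit enumerates injective kind-compatible assignments recursively with
pairwise-distance pruning (|d_model − d_ligand| ≤ tol_i + tol_j), aligns
matched centers by Kabsch (proper rotation, det +1), rejects assignments
where any matched pair exceeds its feature tolerance after alignment, and
maximizes

    score = w · n_matched/n_model + (1 − w) · max(0, 1 − RMSD/RMSD_ref)

with w = 0.5 and RMSD_ref = mean feature tolerance. The exact commercial
formula is proprietary; this form preserves its stated dependence on the
number of matched features and the alignment RMSD, and calibrates so that a
self-defined conformer scores exactly 1. Assignments of 1–2 pairs cannot
determine a rotation (translation-only / underdetermined) and score at most
the match-fraction term. If a `required` feature cannot be matched the
score is 0. Default tolerances: 1.5 Å (aromatic, cationic, donor), 2.0 Å
(hydrophobic).

Conformers come from a pluggable provider; the default is RDKit ETKDGv3
with a fixed random seed, best-of-k (k = 10 for scoring, k = 1–3 inside the
RL loop for speed). Tests bypass embedding with fixed-coordinate fixtures.
Excluded volumes and protein-clash terms are not modeled — the pharmacophore
definition names only the four binding-site features. Pocket-width effects
(the narrower SCH28080-type conduit versus the wider vonoprazan-type one)
are therefore outside what this score can reproduce quantitatively.

Feature coordinates for the real Type A/B/C models are not shipped;
`scripts/extract_pharmacophore.py` derives them from downloaded template
structures via residue anchors (Glu343/795/820 carboxylate centroid,
Ala123 Cβ, Tyr799 ring centroid, conduit midpoint). Tests use toy models
whose features coincide with a real embedded conformer's perceived
features.

## Kinetics

IC50: 4-parameter logistic `bottom + (top−bottom)/(1+(c/IC50)^h)`, fitted
by unweighted trust-region least squares on background-corrected
activities, log-parameterized IC50, bottom constrained ≥ 0, five log-spaced
IC50 starts spanning the concentration range; non-convergence is flagged,
not raised. Standard errors come from the Jacobian at the optimum (delta
method for IC50).

K_i: classical competitive Michaelis–Menten fitted simultaneously across
all inhibitor levels with shared V_max and K_m, all three parameters in log
space (hence positive), Levenberg–Marquardt with seven K_i starts. The
published analysis cites an earlier regression procedure whose weighting is
not reproduced here; unweighted least squares on corrected wells is used,
and a few-percent discrepancy against refits of the original raw data is
expected on that account.

Background subtraction follows the assay design: saturating-blocker wells
define the per-compound background for dose–response plates; K⁺-free wells
at each inhibitor concentration define it for the competition design.
Double-reciprocal (Lineweaver–Burk) series are diagnostic only — shared
1/V_max intercepts and slopes growing as (1 + [I]/K_i) indicate pure
competition. The closed form IC50 = K_i (1 + [K⁺]/K_m) ties the two
estimators together and is asserted in the tests.

Units are molar internally; reports convert to µM/nM for display.

## Structure metrics

Structures are read with gemmi (PDB or mmCIF); only the highest-occupancy
altloc is kept. Cα RMSD pairs residues by chain id + residue number
intersection (no sequence alignment — the compared depositions share
numbering; a documented limitation) and superposes with Kabsch. Contacts
use the conventional cutoffs: polar ≤ 3.5 Å for N/O/S–N/O/S pairs (ligand
halogen to protein N/O pairs inside the polar cutoff are reported as
potential halogen bonds), hydrophobic ≤ 4.0 Å for carbon–carbon pairs;
each atom pair is classified once. Waters and common ions are excluded
from the protein side.

Ligand displacement superposes the two proteins on shared Cα atoms and
measures the centroid shift of the ligands' shared heavy-atom framework,
paired by atom name (falling back to all heavy atoms when the name sets are
disjoint). Atom-name pairing was chosen over a maximal-common-substructure
mapping because coordinate files carry no bond orders and the compared
depositions use consistent ligand nomenclature.

## Synthetic data: what it emulates and what it does not

- **Corpus**: benzyl-ether / benzylamine chemotypes assembled from a block
  grammar (benzene, chloro/fluoro/methylbenzene, pyridine, cyclohexane;
  ether/alkyne/alkyl linkers; amine/hydroxy heads), 1–3 rings deep, with an
  exact, quota-enforced fraction of terminal secondary methylamines. It
  stands in for a large bioactivity database: it exercises tokenization,
  scaffold diversity and the methylamino filter on the relevant chemistry,
  but its grammar is far simpler than drug-like chemical space, so absolute
  validity rates and SA distributions say nothing about full-scale corpora.
- **Plates**: wells drawn from the 4PL or competitive model plus
  multiplicative Gaussian noise (5% default) and a constant non-specific
  baseline removed by background subtraction; 12 concentrations ×
  triplicate for dose–response, 4 × 4 × triplicate for competition. Real
  plates add solubility artifacts and heteroscedastic noise not modeled
  here; passing recovery tests demonstrates estimator correctness, not
  assay robustness.
- **Toy structures**: idealized α-helix Cα traces with one GLU side-chain
  oxygen and a 3-atom ligand at programmed distances, plus a rigidly moved
  / jittered / ligand-shifted copy. PDB text carries 0.001 Å coordinate
  rounding, so "zero" RMSD reads as ~5 × 10⁻⁴ Å after file round-trip.

## Desk-scale problem sizes

The package's own test and reproduction runs use: 3,000-molecule corpus,
25 epochs, hidden size 128 (≥ 90% sampled validity); RL with 2,000 total
steps, 200-step agent cap, batch 24, top-50 harvest (a separate 300-step,
batch-16 run drives the pharmacophore-rewarded triage demonstration, since
conformer embedding dominates its cost); 50–200 simulated plates per
recovery estimate; 100–200-residue toy structures. These sizes
were chosen so a full reproduction completes in minutes on one CPU while
preserving every mechanism of the full-scale workflow (10,000 / 1,000 / 50).
The published structure counts (550/600/650 generated, 71/10/181 selected)
are stochastic outcomes of runs against a proprietary scorer and are
reproduced only as loop arithmetic, not as numeric targets. In the triage
demonstration the RL loop scores with a single embedded conformer and the
harvested set is rescored best-of-10 before selection; how many structures
clear the 0.90 cutoff is strongly seed-dependent at this scale (re-embedded
flexible benzyl ethers typically align to a single-conformer-derived model
at 0.3–0.5 Å feature RMSD, i.e. fit scores in the high 0.8s), so the
reported candidate count can legitimately be zero for some seeds while the
best fit score stays near the cutoff.

## Known limitations

- The recurrent model is intentionally small; no transformer/graph
  alternatives, no transfer learning.
- Pharmacophore perception thresholds are approximations; flexible
  (torsion-sampling) alignment and docking are out of scope.
- Stereochemistry is ignored in scaffold/tabu identity (the source
  procedure does not state whether chirality was considered).
- Whether the 0.90 score cutoff applies to the best conformer or an
  ensemble statistic is not stated; best-conformer is assumed.
- CLI fit reports are JSON/CSV; no plot files are emitted.
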