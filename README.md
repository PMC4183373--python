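# breathescan

Scan promoter sequences for protein-binding / transcription-start-site-like
regions using a mesoscopic model of DNA breathing coupled to a sliding
protein particle.

## The problem and the model

Bacterial transcription start sites (TSSs) and other protein-binding sites
tend to sit in "soft" stretches of the double helix where transient local
openings (breathing bubbles) form easily.  `breathescan` turns that physical
idea into a scanning tool.  The DNA is a one-dimensional lattice of base-pair
opening coordinates `y_n` (the Peyrard–Bishop–Dauxois picture): each pair
feels a Morse potential — deeper for G·C than for A·T — plus a Gaussian
solvent barrier that stabilizes open states, and neighboring pairs couple
through an anharmonic stacking term whose stiffness drops when either pair
opens.  A Brownian particle with coordinate `x` (a generic DNA-binding
protein in its one-dimensional sliding mode) moves along the chain in a
field of Gaussian wells, one per base pair, with an amplitude that grows
with the local opening and saturates for wide-open pairs:

    V_p(x, {y}) = -A Σ_n tanh(y_n / y_sat) · exp(-(x - n)² / 2σ²),  y_n > 0.

The particle seeks out open regions; in turn, pairs under the particle open
more easily, so particle and bubble stabilize each other.  Langevin dynamics
of the joint system (fourth-order stochastic Runge–Kutta) is reduced by PCA,
discretized into a conformational Markov network (particle site × binned
principal components), and the network is clustered into free-energy basins
and macrostates.  Each macrostate — a candidate binding site — is reported
with its occupancy `P`, its free energy relative to the pooled nonspecific
(diffusing) states,

    ΔF = ln(P / P_NS)   [units of k_B T],

and its Shannon entropy over member basins.

## Worked example

```
breathescan synth --length 300 --background-at 0.4 --window 194 30 0.95 \
    --seed 3 --out promoter.fa
breathescan analyze --fasta promoter.fa --seed 3 --out results/ \
    --config examples/desk_config.json
```

With the bundled desk-scale configuration (five realizations of 8×10⁴ time
units each) this prints, for the synthetic promoter with an A/T-rich window
planted at sequence positions 194–224:

```
synthetic: 7 macrostates, P_NS=0.0418
label	site	P	dF_kBT	S	n_basins	tss_match
-95	215	0.586413	2.6405	2.5641	16
-212	98	0.130737	1.1397	1.8904	8
-93	217	0.11105	0.9765	0.5449	2
-20	290	0.068363	0.4913	1.9101	7
...
```

The heaviest macrostate (occupancy 0.59, ΔF ≈ 2.6 k_BT above the
nonspecific background) sits at simulated-chain site 215 = sequence
position 205 (label −95, counted upstream from the sequence end) — inside
the planted window, which plays the role of a TSS.  The particle-visit
histogram peaks in the same region.  The weaker states are background
A/T-rich patches the particle also visits.  Python users can do the same
through `breathescan.analyze_promoter`; see the docstrings and
`docs/methods.md` for every stage and parameter.

A second workflow, `breathescan gene-pca`, runs the chain without the
particle over a whole gene and reports where the leading breathing modes
localize (promoter vs body), reproducing the observation that most
sequence-driven flexibility concentrates upstream of the coding region.

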