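# polyads

Automated detection and classification of **polyadic base multiplets** —
pentads, hexads, heptads and octads — in nucleic-acid 3D structures.

## The problem

Beyond Watson–Crick duplexes, DNA and RNA fold into planar, ring-like
arrangements of three or more bases joined by hydrogen bonds, usually
through their Hoogsteen or sugar edges. The best-known member of this
family is the guanine tetrad (G-quartet), the building block of
G-quadruplexes. Tetrads are frequently *extended in their own plane* by
additional nucleotides — an adenine completing a sheared G:A pair turns a
tetrad into a pentad or hexad; four such extensions make an octad. These
extensions enlarge the planar stacking surface and can strongly stabilize
the quadruplex, yet they are easy to miss by eye and are not annotated by
standard base-pair tools. `polyads` finds them automatically from atomic
coordinates (PDB or mmCIF, gzip-transparent), for structural biologists
cataloguing quadruplex architecture and for anyone designing or validating
G-rich constructs.

## Method

For a structure *S*, base pairs, stacking contacts and strand continuity
are collected (built-in geometric annotator, or an imported annotation
file). Tetrads are chordless 4-cycles of paired, near-coplanar bases; they
are chained into vertical stacks through face-to-face stacking contacts.
Every nucleotide *N* near a tetrad *T* (innermost base atom A<sub>in</sub>
and glycosidic nitrogen A<sub>out</sub> both within 13 Å of the tetrad
centroid *C*) is then tested against four criteria, in order:

1. **Connectivity** — ConCount(N,T) ≥ 2, where ConCount counts tetrad
   members reached by base pairing or by covalent strand continuity, and
   PairCount ≤ ConCount counts the base-paired ones.
2. **Planarity** — Tilt(N,X<sub>k</sub>) = arccos|n̂<sub>N</sub>·n̂<sub>X<sub>k</sub></sub>|
   against each member X<sub>k</sub> (k = 1..4):
   mean ≤ TT<sub>avg</sub> = 40° and max ≤ TT<sub>max</sub> = 50°.
3. **Proximity** — Dist(A<sub>in</sub>, C) ≤ 13 Å, and the candidate's
   distances to its two nearest members must not differ by more than 2 Å
   (ring symmetry).
4. **Height** — ΔH(C, A, X<sub>k</sub>) = (C − A)·n̂<sub>X<sub>k</sub></sub>
   for A ∈ {A<sub>in</sub>, A<sub>out</sub>}: every |ΔH| ≤ HT<sub>max</sub> = 3.7 Å
   and each probe's mean ≤ HT<sub>avg</sub> = 3.15 Å.

Survivors are scored from their six threshold margins m<sub>i</sub>
(mean/max tilt, mean/max |ΔH<sub>in</sub>|, mean/max |ΔH<sub>out</sub>|):

    Score(N,T) = ( Σᵢ wᵢ·(mᵢ·100)^pᵢ ) / 2 + PairCount,
    w = (1.0, 0.5, 1.0, 0.75, 1.0, 0.75),  p = (2, 2, 1.75, 1.75, 1.75, 1.75)

Scores are used ordinally: a nucleotide eligible for several tetrads is
assigned to its best-scoring one, and within each stack all polyads are
trimmed to a common order (lowest scores dropped first, preserving angular
symmetry) unless `--lax-order` is set. Results are classified by residue
count: pentad (5), hexad (6), heptad (7), octad (8).

See `docs/methods.md` for assumptions, parameter rationale and limits.

## Worked example

```bash
python examples/detect_polyads.py
```

builds a dimeric quadruplex core — two stacked G-tetrads, each extended by
two adenines — and runs the pipeline on it:

```
polyads 0.1.0 — scratch_example/dimeric_hexads.pdb (model 1)
hexad (order 6) on tetrad A/1:A/3:A/4:A/6 [stack 0, layer 1]
  + A/2 (A)  score=8539440.4  pairs=1 links=2  tilt_avg=10.0deg  dh_in_avg=0.50A  dh_out_avg=0.20A  dist=8.01A
  + A/5 (A)  score=8539440.4  pairs=1 links=2  tilt_avg=10.0deg  dh_in_avg=0.50A  dh_out_avg=0.20A  dist=8.01A
hexad (order 6) on tetrad B/1:B/3:B/4:B/6 [stack 0, layer 0]
  + B/2 (A)  score=8539546.2  pairs=1 links=2  tilt_avg=10.0deg  dh_in_avg=0.50A  dh_out_avg=0.20A  dist=8.01A
  + B/5 (A)  score=8539546.2  pairs=1 links=2  tilt_avg=10.0deg  dh_in_avg=0.50A  dh_out_avg=0.20A  dist=8.01A
stacked tetrads:
  stack 0 layer 0 (end): B/1:B/3:B/4:B/6 — polyad core
  stack 0 layer 1 (end): A/1:A/3:A/4:A/6 — polyad core
```

Both planted hexads are recovered: each adenine extension forms one base
pair with a tetrad guanine plus one covalent link to the next (`pairs=1
links=2`), lies 10° out of parallel with the member planes, and sits
essentially in the tetrad plane (mean heights 0.5/0.2 Å against 3.15 Å
allowed). Residues are written `chain/number` in author numbering.

The same analysis is available as a command:

```bash
polyads --input structure.cif.gz --format json
polyads --input structure.pdb --lax-order --tilt-avg 35 --output report.txt
```

`--height-max/--height-avg`, `--tilt-max/--tilt-avg`,
`--dist-in-max/--dist-out-max` override the thresholds above;
`--annotations pairs.json` substitutes an external base-pair annotation
for the built-in detector; exit status is 0 even when no motif is found
(an empty report is a result). Other examples: `sweep_planted_tilt.py`
(detection flipping at the planarity gate), `external_annotations.py`
(annotation import round-trip).

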