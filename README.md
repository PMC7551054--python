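# bromonet

Molecular networking and MS/MS annotation of brominated cyclic
depsipeptides — the computational workflow by which new bromoalterochromide
analogs are recognized in microbial-interaction metabolomics.

Bromoalterochromides are pentapeptide macrolactones from marine
*Pseudoalteromonas*: a brominated aryl-polyene acyl chain is amide-linked to
a Thr-X-Asn-Asn-Ile/Leu pentapeptide whose ring closes from the threonine
side-chain oxygen onto the C-terminal carbonyl. They are produced more
intensely when the bacteria grow in interaction with fungal and bacterial
testers. `bromonet` implements, as a tested reusable library:

* **Exact-mass chemistry** (`bromonet.chemformulas`) — molecular-formula
  arithmetic, protonated/sodiated ion m/z with per-charge electron
  correction, isotopologue patterns by convolution of elemental isotope
  distributions, bromine-count inference from the characteristic Br
  doublet/triplet, and bounded exhaustive molecular-formula enumeration
  with ppm and RDBE filters.
* **A cyclic-depsipeptide fragmentation model** (`bromonet.depsipeptide`) —
  b/y ladders from the two ring-opening sites (the macrolactone ester bond
  and the threonine O–C bond) plus the aryl-polyene elimination ion that
  dominates these spectra. Singly protonated fragments obey
  `b_k + y_{n-k} = [M+H]+ + 1.00728`.
* **Spectrum/feature I/O** (`bromonet.spectra_io`) — MGF read/write,
  MZmine-style isotope grouping (0.005 Da / 0.20 min) and join alignment
  (0.02 Da / 0.2 min).
* **Feature-based molecular networking** (`bromonet.networking`) — modified
  cosine with exact optimal peak matching (peaks match directly or shifted
  by the precursor difference), GNPS-style edge rules (cosine > 0.70,
  ≥ 5 matched peaks, top-10 edges per node), molecular families as
  connected components, GraphML export.
* **Dereplication and analog discovery** (`bromonet.annotation`) — library
  matching by precursor m/z, classification of edge mass offsets
  (CH₂ 14.0157, C₂H₂ 26.0157, Br−H 77.9105, Na−H 21.9819) with propagation
  along the network, fragment-level verification, and sample-group
  provenance (monoculture / interaction / shared / control).
* **A ground-truth simulator** (`bromonet.synthetic_data`) and a thin CLI
  (`bromonet simulate | network | annotate | report`).

## Worked example

```python
from bromonet import IonSpec, enumerate_formulas, ion_mz, parse_formula

mono = ion_mz(IonSpec(parse_formula("C39H53N7O10Br"), "as-is"))
di   = ion_mz(IonSpec(parse_formula("C39H52N7O10Br2"), "as-is"))
print(f"{mono:.4f} {di:.4f} {di-mono:.4f}")
# 858.3032 936.2137 77.9105
```

The first two numbers are the calculated [M+H]⁺ values of the mono- and
di-brominated Thr-Ile-Asn-Asn-Ile/Leu depsipeptides; their difference is
the bromine-for-hydrogen substitution step that links the two analog
clusters in the network. Running the full discovery workflow on the
simulated interaction study (`python examples/04_molecular_networking.py`)
prints:

```
spectra read: 68
network nodes: 68
network edges: 403
molecular families: 9
library matches: 36
new analogs: 19
unknown nodes: 13
provenance monoculture-only: 3
provenance interaction-only: 3
provenance shared: 12
provenance control: 2
```

All twelve planted depsipeptide analogs fall into a single molecular
family; the four unknown D-series compounds are called as new analogs of
the known A series (CH₂ homologation) and of each other (Br−H), while the
decoy spectra remain unknown. The `examples/` directory holds one short
script per capability (exact masses, fragmentation, isotope patterns,
networking).

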