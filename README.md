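# fuelkit

A toolkit for modeling Gene Ontology molecular functions with **FueL**, the
Function Modeling Language — a UML-profile-style notation in which a function
is specified by its *goal achievement* rather than by free text. fuelkit is
aimed at ontology engineers and curators who want the structure that is
implicit in the Molecular Function Ontology (MFO) made explicit, checkable,
and drawable: which is_a links are operand specializations, which add or
refine a mode of realization, which terms are pure grouping artifacts that
could be dropped, and which functions a grouping term should collect but
currently does not.

## The model

A molecular function *f* carries a goal achievement

> GA(f) = ⟨input, output, operand, mode, doer, process⟩

where *input* and *output* are situation categories given as templates over
participant slots (e.g. `{operand} is on one side of the membrane`), *operand*
is the category acted on (patient), *doer* the acting category, *mode* a
constraint on *how* the transition is realized, and *process* the biological
process realizing the GA (the ontology's `part_of` target).

Structural (intensional) subsumption: function *y* subsumes *x* iff
GA(*y*) subsumes GA(*x*), i.e.

1. input(*y*) ⊒ input(*x*) and output(*y*) ⊒ output(*x*) slot-wise over the
   participant taxonomy (identical templates required);
2. operand(*y*) is absent, or both operands are present with
   operand(*y*) ⊒ operand(*x*);
3. mode(*y*) is absent, or both modes are present with
   mode(*x*) specializing mode(*y*).

Each declared is_a link is then classified with the pattern stereotypes
«operand-spec» (strict operand refinement), «mode-added» (child gains a mode),
«mode-spec» (strict mode refinement), plus `plain` (structurally equal GAs)
and `unsupported` (the declared direction has no structural backing). An
experimental «output-spec» facet for output-only refinement is off by default.

On top of the classifier sit the refactoring analyses: grouping-artifact
detection (a term whose ≥2 children differ only in operands and whose parent
already subsumes them all), closure-preserving drop-and-rewire, reattachment
proposals, missing-process listing, and specialization-style profiling
(mode-dominant vs operand-dominant term families).

## Worked example

fuelkit ships the transmembrane-transporter segment of MFO as an OBO file plus
a YAML *sidecar* carrying the FueL structure (OBO has no slot for it). Emit the
fixture and classify its links:

```sh
$ fuel fixtures --name fig5 --emit demo
$ fuel classify demo/fig5.obo demo/fig5.sidecar.yaml
child       parent      facets
GO:0005402  GO:0008324  mode-added
GO:0005402  GO:0015291  mode-spec,operand-spec
GO:0008324  GO:0015075  operand-spec
GO:0015075  GO:0022891  operand-spec
GO:0015144  GO:0022891  operand-spec
GO:0015238  GO:0022857  operand-spec
GO:0015291  GO:0022804  mode-spec
GO:0022804  GO:0022857  mode-added,operand-spec
GO:0022891  GO:0022857  operand-spec
GO:0090482  GO:0022857  operand-spec
```

Reading: cation transmembrane transport (GO:0008324) under ion transmembrane
transport (GO:0015075) is a pure operand specialization; active transmembrane
transport (GO:0022804) under transmembrane transport (GO:0022857) both narrows
the operand and adds a mode; secondary active transport (GO:0015291) refines
that mode.

The refactoring analysis then flags GO:0022891 (*substrate-specific
transmembrane transporter activity*) as a grouping artifact — its children
differ only in operands and its parent GO:0022857 already subsumes them — and
proposes the functions it should collect but does not:

```sh
$ fuel refactor demo/fig5.obo demo/fig5.sidecar.yaml
kind               term        ... proposal                         reason
grouping-artifact  GO:0022891  ... drop GO:0022891                  children differ only in their operands
reattachment       GO:0022891  ... add GO:0015238 is_a GO:0022891   structurally subsumed but not declared
reattachment       GO:0022891  ... add GO:0090482 is_a GO:0022891   structurally subsumed but not declared
...

$ fuel refactor demo/fig5.obo demo/fig5.sidecar.yaml --drop GO:0022891
drop         GO:0022891
remove-link  GO:0015075  GO:0022891
remove-link  GO:0015144  GO:0022891
remove-link  GO:0022891  GO:0022857
add-link     GO:0015075  GO:0022857  operand-spec
add-link     GO:0015144  GO:0022857  operand-spec
```

The drop rewires the two orphaned children straight to GO:0022857, classifies
the new links, and provably preserves the is_a closure over the surviving
terms. Diagrams come from `fuel render` (`--notation compact|extended`,
`--format plantuml|dot`), which emits the stereotyped class-diagram text of
either FueL notation.

The same functionality is available as a library:

```python
from fuelkit import classify_fragment, find_grouping_artifacts
from fuelkit.fixtures import fig5_fragment

frag = classify_fragment(fig5_fragment()).fragment
print([str(c.term) for c in find_grouping_artifacts(frag)])  # ['GO:0022891']
```

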