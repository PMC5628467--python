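# Methods

This note documents the modeling decisions behind fuelkit: what exactly the
structures mean, where the design was genuinely open and which choice was
made, what the synthetic fragments do and do not emulate, and the known
limitations.

## Concept structure

A function concept is a GO-style term (id, name, definition, synonyms) plus an
optional goal achievement (GA). The GA is deliberately *categorial*: it
describes situation categories and participant categories, never individuals.

**Situations as templates.** Input and output situations are stored as a text
template with named participant slots plus a binding per slot
(`"{operand} is on one side of the membrane"`, operand → *cation*). The
motivating observation is that the situation descriptions of related functions
differ only in the participant category; lifting that category into a slot
makes situation comparison decidable: two situations are comparable iff their
templates are identical after whitespace normalization, and comparison then
reduces to category subsumption slot by slot. Templates are *not* unified up
to slot renaming — no modeled case requires it, and renaming-insensitive
matching would silently equate situations a curator wrote as different.

**Absent operand/mode.** An absent operand or mode is a distinct state, not a
synthetic top element in the taxonomy. The *semantics* layer treats absence on
the general side as the universal restriction (anything satisfies it) and
absence on the specific side, facing a present general constraint, as a
failure (the specific would be less constrained than its ancestor). Keeping
"absent" out of the data model avoids inventing taxonomy nodes that no
ontology declares.

**Doers** are recorded and rendered but excluded from the subsumption
criterion: doers accompany modes descriptively and ground no specialization
pattern. `audit_links` reports doer mismatches informationally. Whether a doer
must participate in the input situation is left unconstrained.

## Subsumption and classification

`ga_subsumes` is the conjunction of four conditions (inputs, outputs, operand,
mode) given in the README. It is reflexive and — over DAG taxonomies —
transitive, so the layer is a preorder. The *classifier* applies strict
variants: a facet is only awarded for proper refinement (operand or mode
strictly below, mode present vs absent). Structurally equal GAs classify as
`plain` rather than as a degenerate specialization, so that duplicated
structure is surfaced by the refactoring analyzer instead of being disguised
as a pattern instance. A declared link whose direction has no structural
backing gets the singleton `unsupported`.

Two asymmetric conventions are worth stating:

* *parent operand absent, child operand present* counts as `operand-spec`
  (there is no separate "operand-added" stereotype; the child's operand is a
  strict refinement of the parent's universal restriction);
* `mode-added` and `mode-spec` are mutually exclusive by definition
  (they condition oppositely on the parent's mode).

`output-spec` — specialization purely through a strictly narrower output
situation, with operands and modes contributing nothing — is implemented but
off by default (`ClassifyOptions.enable_output_spec`). It targets
regulator/activator/inhibitor-style families; it is marked experimental
because it is a plausible generalization rather than an established pattern,
and enabling it can only add a facet where the default classifier would say
`plain`.

## Refactoring analyses

**Grouping artifacts.** The operationalization is deliberately conservative:
a term `g` is a candidate iff (i) `g` has ≥ 2 children, all of whose links
carry facets ⊆ {operand-spec}; (ii) `g` has a parent `p` whose link carries
facets ⊆ {operand-spec, plain}; (iii) `p` structurally subsumes every child of
`g` (rewiring is sound). Candidates are *reported*, never auto-applied — the
decision belongs to the ontology's curators. Descendants of a candidate that
add or specialize a mode the candidate lacks (e.g. a symporter sitting under a
purely operand-grouping term through one of its parents) are listed as notes:
their membership is questionable, and the tool takes no stance.

**Drop-and-rewire.** `apply_drop` removes a term and adds a child→parent link
only where the remaining graph has no path already, so a transitively reduced
link set stays reduced. The postcondition — the is_a closure over surviving
terms equals the original closure restricted to them — is checked by brute
reachability in the tests and in the acceptance script. Dropping a root is
refused (there is nowhere to rewire to).

**Reattachment.** For a group term `g`, every annotated function that `g`
structurally subsumes, that is not `g` itself, not an ancestor of `g`, and has
no declared path to `g`, is proposed. This intentionally over-approximates the
minimal curatorial suggestion: structurally valid placements that curators may
reject for other reasons are still worth listing.

**Profiling.** A term's specialization style over its direct child links is
*mode-dominant* when a strict majority of classified child links carry a mode
facet and at most one is operand-spec-only, *operand-dominant* symmetrically,
else *mixed* (*undetermined* with no classified child links). The majority
threshold and the off-style allowance (`max_offstyle=1`, accommodating
families where exactly one child also adds a mode) are keyword-configurable.

## File formats

OBO 1.2 `[Term]` stanzas carry the ontology-visible part; parsing takes the
first quoted string of `def:` (dbxref lists ignored), preserves synonym lines
verbatim (scope markers and all), skips obsolete terms with a warning, and
fails with a line number on a stanza without an id. Only `is_a` and `part_of`
receive semantics; `part_of` on a function names the process realizing its GA
(a sidecar `process` value wins over `part_of`, with a warning). All other
relationships are preserved verbatim and re-emitted. A stanza whose id is only
ever referenced as a process — a `part_of` target or sidecar `process` value,
never annotated or linked as a function — is read as a process term, not a
function.

The sidecar is YAML (any JSON-compatible subset parses identically) with
top-level keys `functions`, `participants`, `modes`, `externals`, plus one
optional per-function key `bearer` naming the entity that plays the function
role (needed to round-trip the extended notation's «plays» association).
References must resolve within the sidecar's taxonomies or be declared in
`externals`; duplicate annotations are rejected at load time. Writing is
deterministic (sorted keys), and `assemble → write → parse → load → assemble`
is the identity on every packaged and generated fragment.

## Stereotype registry

The profile declares 15 stereotypes for functions and function structure and
8 for decomposition, subsumption and dependencies, but only seven names are
fixed by the material modeled here (Function, has-goal-achievement, has-input,
has-output, operand-spec, mode-added, mode-spec). The default registry is an
explicit reconstruction: the structure side holds the classifier stereotypes
(Function, GoalAchievement, InputSituation, OutputSituation, Mode, Operand,
Doer, Bearer) and the structural associations (has-goal-achievement,
has-input, has-output, has-operand, has-doer, has-mode, plays) — exactly 15 —
and the relation side holds the four pattern stereotypes plus decomposition/
dependency placeholders (subfunction-of, depends-on, requires, triggers) —
exactly 8. This is the only partition under which the named stereotypes and
the extended notation's edge set fit the declared split; `plays` sits on the
structure side by choice, as the bearer belongs to function *ascription*. The
registry is a value, replaceable wholesale; renderers fail fast on any
stereotype not in the active registry.

## Packaged fragments

Each packaged fragment reconstructs one discussed MFO segment from the term
ids, names and structural descriptions available; ids not fixed by the source
material use the fixture-local `FX:` prefix rather than guessed GO ids. Two
modeling choices in the transporter segment deserve a note:

* GO:0022804's operand is "a specific substance or group of substances" —
  equal to GO:0022891's — so its link to GO:0022857 carries both `mode-added`
  and `operand-spec`. GO:0015291 shares that operand, making its link to
  GO:0022804 a pure `mode-spec`; the word *solute* used in the active-transport
  situation descriptions remains in the participant taxonomy but is not bound
  as any fig5 operand (binding it would add a spurious operand-spec facet to a
  link that is a pure mode refinement).
* GO:0005402 (*cation:sugar symporter activity*) binds *cation* as operand
  with the symport mode, under both GO:0008324 and GO:0015291. This places it
  under the grouping term via an operand path while its mode arrives via the
  other parent — the configuration whose "pure membership" under the grouping
  term is questionable, reported as a note.

The electron-carrier fragment is deliberately partial (two of the family's
children) and is used for rendering demonstrations only.

## Random planted fragments

`generate_random(seed, n_functions, taxonomy_depth)` builds a binary
participant tree, a small mode tree, and then grows a function forest by
derivation: each new function copies a randomly chosen existing function's GA
and applies one (sometimes two) definition-instantiating edits — strict
operand refinement, mode addition to a mode-less ancestor, strict mode
refinement — or no edit. The applied edit set *is* the planted facet label of
the created link, which makes the generator an exact oracle for the
classifier: recovery must be 100%, and is, over 200 fragments in both the test
suite and the acceptance script.

What the generator does not emulate: multi-parent functions, unannotated
terms, links declared against the structural direction, situation-template
variety within one fragment, and taxonomies with multiple inheritance
(participant DAGs are exercised separately in the subsumption tests). Passing
the planted-recovery suite therefore shows the classifier implements its
definitions exactly; it does not show how often real MFO links are annotatable
cleanly enough to classify — that remains manual curation work.

Problem sizes (12–30 functions per random fragment, 200 seeds) keep the whole
suite and the acceptance run within seconds while exercising every code path;
the properties checked are size-independent identities, not statistical
estimates, so larger fragments would add time, not information.

## Known limitations

* Subsumption compares situations only under identical templates; two
  semantically equivalent paraphrases are incomparable by design.
* The sidecar is the only carrier of FueL structure; nothing is inferred from
  OBO definitions (no text mining).
* `part_of` on an *unannotated* function has no GA to land in and survives
  only at the stanza level, not in the fragment.
* Extensional (instance-based) subsumption, OWL translation, and XMI/UML-tool
  interchange are out of scope.
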