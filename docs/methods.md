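# Methods

## The matching model

A code dictionary is a table of (code, description) rows; clinical codes
are hierarchical, so a code prefix denotes a clinical subtree. A query is
a set of inclusion terms — code-stubs matched as case-sensitive prefixes
of the code field, and word-stubs matched as substrings of the
description — plus exclusion stubs. The hit set is

```
hits = (∪ over include terms of their matches) \ (∪ over exclusion stubs of their matches)
```

A plus-joined word term is a conjunction (every stub must occur somewhere
in the description); an underscore inside a stub is exactly one literal
space (phrase matching). There is no word-boundary logic, no whitespace
normalisation beyond the underscore mapping, and no fuzzy matching: the
matcher is intended to over-retrieve, and precision is recovered by the
human review step, not by the algorithm.

Consequences worth knowing:

* substring matching is monotone — adding an include term can only grow
  the hit set, adding an exclusion can only shrink it, and a longer stub's
  hits are a subset of any of its substrings' hits;
* exclusions veto *all* hits, including those matched via a code stub.
  The alternative (exclusions applying only to word-stub hits) is
  defensible, but exclusions exist to thin the review workload and a veto
  that cannot veto is surprising;
* description matching is case-insensitive by default (`casefold`),
  configurable per search. Case-insensitivity serves the "miss nothing"
  intent; code matching stays case-sensitive because clinical codes are
  case-significant.

## Review and tiers

Review categories are a fixed eight-label vocabulary (seven substantive
categories plus `not_relevant`); unknown labels are rejected at ingest
because review files are hand-edited and a silently dropped typo would
surface as a wrong case definition much later. Tier policies are
configuration: the conservative tier defaults to `{diagnosis}` — each code
must indicate the condition and that alone — but conditions with exclusive
drug associations may legitimately widen it. The containment relations
(QOF minus exceptions ⊆ conservative ⊆ speculative) are normative, so
`check_supersets` reports violations rather than raising; the CLI offers
`--strict`. Every built list carries provenance (content hash of the
reviewed rows, input file hashes from the CLI) because a code list that
cannot be traced to its inputs cannot be audited.

## Case finding

A patient is a case when their events contain at least `min_codes`
occurrences of list codes; onset is the earliest matching event date.
Occurrences, not distinct codes, are counted — a chronic patient
re-receives the same code — with a `distinct_dates` option to guard
against duplicate same-day entries when a stricter threshold is used.
Event-to-list matching is exact string equality; prefix semantics live
only in the search stage. Events whose codes appear in no dictionary are
tolerated (real extracts contain them) and never match.

## Rates

Financial years run 1 April – 31 March ("2000/01"). For year Y:

* prevalence = (registered patients with onset ≤ last day of Y) /
  (patients whose registration interval overlaps Y);
* incidence = (patients with onset inside Y and registered during Y) /
  (patients registered during Y with no onset before Y starts).

The any-overlap denominator is the simplest defensible choice; mid-year
census or person-years denominators would shift levels slightly without
affecting the between-code-list comparisons the module exists for, and
the definition is isolated behind the module surface for extension. A
patient whose onset year has no registration overlap is excluded from
incidence numerators and logged (they remain at risk while registered
pre-onset). Zero denominators yield NaN rates, never 0. Rates are stored
as exact ratios and rendered as percentages to 4 decimal places. One
registration spell per patient is assumed; multi-spell registration is
out of scope.

## Synthetic data

`generate_lookup` builds a dictionary around a query: *relevant* rows
embed an include stub as a standalone token (or carry a code with a
requested prefix), *trap* rows bury a stub inside a longer word —
manufactured "sunstroke"-style false positives — and the remainder match
nothing (rejection-sampled, since stub-free words can still recreate a
phrase across a word boundary). The description corpus is a packaged
~120-word clinical-flavoured list; no external dictionary is needed.

`generate_population` builds a closed cohort: every patient registers
1–5 years before the first financial year and stays registered, so planted
parameters identify directly with the rate definitions above. Each
patient is independently baseline-prevalent with probability `prevalence`
(onset uniform in the two years before the study) or incident in year *k*
with probability `annual_incidence` per year (onset uniform within the
year). Assigning incidence unconditionally rather than conditional on
being case-free biases the measured rate by a factor ≈ 1/(1 − prevalence
− k·incidence), which at the default 0.8% / 0.05% is far below one
Monte-Carlo standard error. Sex is assigned 50/50 male/female.

Case events default to a **per-patient primary code**: one list code drawn
uniformly per case and repeated across their 1 + Poisson(2) events, with
the first event exactly at onset. This mirrors how a chronic diagnosis is
re-recorded at follow-up (a handful of codes account for most identified
cases) and makes the narrow-vs-broad list comparison clean: a patient is
either captured by the subset list or missed entirely, rather than
drifting into a later incident year depending on which event happens to
carry which code. The alternative `event_code_style="mixed"` draws every
event's code independently — useful for exercising onset-shift behaviour
in the case finder, but not the default because per-event i.i.d. coding is
the less realistic model. All patients also receive Poisson(3) noise-coded
events, and ~10% of events are tagged as referrals.

What the generator does **not** emulate: practice-level coding variation,
policy-driven step changes in recording, comorbidity structure,
consultation-rate dynamics, registration churn and multi-spell patients,
or any real terminology's code distribution. Passing tests therefore show
the pipeline's logic is correct under its stated definitions, not that
rates computed from a real extract are unbiased.

## Default study conditions

The simulation used by the acceptance checks and `examples/04`: 20,000
patients, twelve financial years (2000/01–2011/12), baseline prevalence
0.8%, annual incidence 0.05%, a ten-code conservative list with a
five-code subset standing in for a QOF register definition. At these
sizes a full simulate → extract → rates cycle runs in a few seconds on
one core; planted-parameter recovery is asserted within 3 binomial
standard errors, with the first-year prevalence compared against
prevalence + one year's incidence (onsets during the first year count by
its end).

## Numerical and tie-break choices

* Search hits are sorted by (code, description, row_id); duplicated codes
  keep distinct row ids so synonym rows survive.
* Duplicate codes at list-build or merge time keep the first-seen
  category; conflicts are logged, never silent.
* Dates are ISO-8601 throughout; impossible dates fail at read time.
* Files are UTF-8 with a logged Latin-1 fallback for legacy dictionary
  exports; delimiters are explicit configuration, never sniffed.
* All generators take an explicit integer seed (single `numpy` Generator
  stream per call) and record it in their truth sidecars; fixed-seed runs
  are byte-identical end to end.

## Known limitations

No free-text (narrative) search; no terminology synonym expansion beyond
the rows the dictionary carries; no age standardisation, exact confidence
intervals or trend testing; no multi-spell registration or data-quality
("acceptable patient") filtering. The review step itself is a human
process — the toolkit automates everything around it.
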