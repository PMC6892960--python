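"""Independent brute-force oracles used by the tests.

Everything here works directly off the raw term tuples and record fields,
deliberately avoiding the package's own traversal, inverse-resolution and
query machinery, so that agreement between the two routes is meaningful.
"""

from __future__ import annotations

import random

from ecointeractions import Dataset, InteractionRecord, QueryCriteria
from ecointeractions.vocabulary import InteractionTypeTerm


def naive_descendants(terms: list[InteractionTypeTerm], label: str) -> set[str]:
    """Reflexive-transitive closure down the parent list, by fixpoint scans."""
    canon = {t.label.lower(): t.label for t in terms}
    out = {canon[label.strip().lower()]}
    changed = True
    while changed:
        changed = False
        lower = {o.lower() for o in out}
        for t in terms:
            if (
                t.parent_label is not None
                and t.parent_label.strip().lower() in lower
                and t.label not in out
            ):
                out.add(t.label)
                changed = True
    return out


def naive_inverse(terms: list[InteractionTypeTerm], label: str) -> str:
    by_label = {t.label.lower(): t for t in terms}
    inv_label = by_label[label.strip().lower()].inverse_label
    return by_label[inv_label.strip().lower()].label


def _status_ok(status, in_set, not_in_set):
    key = status.strip().lower()
    if in_set is not None and key not in {s.lower() for s in in_set}:
        return False
    if not_in_set is not None and key in {s.lower() for s in not_in_set}:
        return False
    return True


def _view_matches(subject, obj, itype, record, crit: QueryCriteria, type_set):
    if type_set is not None and itype.strip().lower() not in type_set:
        return False
    if crit.taxon_name is not None:
        roles = {"subject": [subject], "object": [obj], "either": [subject, obj]}[
            crit.taxon_side
        ]
        hit = any(
            r.taxon.name == crit.taxon_name
            or crit.taxon_name in r.taxon.classification_path
            for r in roles
        )
        if not hit:
            return False
    if not _status_ok(
        subject.establishment_status, crit.subject_status_in, crit.subject_status_not_in
    ):
        return False
    if not _status_ok(
        obj.establishment_status, crit.object_status_in, crit.object_status_not_in
    ):
        return False
    if crit.interaction_status_in is not None:
        if record.interaction_status.strip().lower() not in {
            s.lower() for s in crit.interaction_status_in
        }:
            return False
    if crit.importance_in is not None:
        if record.importance is None or record.importance.strip().lower() not in {
            s.lower() for s in crit.importance_in
        }:
            return False
    if crit.locality_name_contains is not None:
        loc = record.locality
        if loc is None or loc.name is None:
            return False
        if crit.locality_name_contains.lower() not in loc.name.lower():
            return False
    return True


def naive_filter(dataset: Dataset, crit: QueryCriteria) -> list[InteractionRecord]:
    terms = list(dataset.vocabularies.interaction_types.terms)
    inverse = {t.label.lower(): t.inverse_label for t in terms}
    type_set = None
    if crit.interaction_type is not None:
        if crit.expand_hierarchy:
            labels = naive_descendants(terms, crit.interaction_type)
        else:
            labels = {t.label for t in terms if t.label.lower() == crit.interaction_type.lower()}
        type_set = {l.lower() for l in labels}
    out = []
    for record in dataset:
        views = [(record.subject, record.object, record.interaction_type)]
        if crit.match_inverse:
            views.append(
                (
                    record.object,
                    record.subject,
                    inverse[record.interaction_type.lower()],
                )
            )
        if any(_view_matches(s, o, t, record, crit, type_set) for s, o, t in views):
            out.append(record)
    return out


_TYPE_LABELS = (
    "eats", "eaten by", "parasite of", "parasitized by", "ectoparasite of",
    "ectoparasitized by", "interacts with", "host of",
)
_TAXA = (
    "Phasmida", "Lepidoptera", "Phthiraptera", "Aves", "Mammalia",
    "Carausius morosus", "Columba livia", "Rosa sp.", "Plantae",
)
_ORG_STATUSES = (
    "Native", "Introduced", "Naturalised", "Invasive", "Managed", "Captivity", "unknown",
)
_INT_STATUSES = (
    "Interaction recorded in the wild",
    "Interaction recorded in captivity",
    "Interaction recorded in captivity from wild caught specimens",
    "Interaction recorded in captivity from captive bred specimens",
    "unknown",
)
_IMPORTANCES = (
    "Economic", "Economic (crop pest)", "Economic (timber pest)",
    "Economic (pest control)", "Medical", "Veterinary",
)
_LOCALITY_SUBSTRINGS = ("San", "India", "Thailand", "london", "Kingdom")


def random_criteria(rng: random.Random) -> QueryCriteria:
    """A random, internally consistent set of faceted-search criteria."""
    kwargs: dict = {
        "expand_hierarchy": rng.random() < 0.7,
        "match_inverse": rng.random() < 0.7,
    }
    if rng.random() < 0.6:
        kwargs["interaction_type"] = rng.choice(_TYPE_LABELS)
    if rng.random() < 0.4:
        kwargs["taxon_name"] = rng.choice(_TAXA)
        kwargs["taxon_side"] = rng.choice(("subject", "object", "either"))

    def status_sets(prefix: str) -> None:
        in_set = not_in_set = None
        if rng.random() < 0.3:
            in_set = frozenset(rng.sample(_ORG_STATUSES, rng.randint(1, 3)))
        if rng.random() < 0.3:
            pool = [s for s in _ORG_STATUSES if in_set is None or s not in in_set]
            if pool:
                not_in_set = frozenset(rng.sample(pool, min(len(pool), rng.randint(1, 2))))
        kwargs[f"{prefix}_status_in"] = in_set
        kwargs[f"{prefix}_status_not_in"] = not_in_set

    status_sets("subject")
    status_sets("object")
    if rng.random() < 0.25:
        kwargs["interaction_status_in"] = frozenset(
            rng.sample(_INT_STATUSES, rng.randint(1, 2))
        )
    if rng.random() < 0.2:
        kwargs["importance_in"] = frozenset(rng.sample(_IMPORTANCES, rng.randint(1, 2)))
    if rng.random() < 0.2:
        kwargs["locality_name_contains"] = rng.choice(_LOCALITY_SUBSTRINGS)
    return QueryCriteria(**kwargs)


def random_forest(rng: random.Random, n_terms: int) -> list[InteractionTypeTerm]:
    """A random valid vocabulary: inverse pairs (plus one self-inverse when
    *n_terms* is odd) and random single-parent links to earlier terms."""
    terms: list[InteractionTypeTerm] = []
    labels: list[str] = []
    i = 0
    while i < n_terms:
        label = f"relation {i:04d}"
        if i + 1 < n_terms:
            inv = f"relation {i + 1:04d}"
        else:
            inv = label  # odd count: last term is symmetric
        for this, other in ((label, inv), (inv, label)) if inv != label else ((label, label),):
            parent = rng.choice(labels) if labels and rng.random() < 0.8 else None
            terms.append(
                InteractionTypeTerm(
                    label=this,
                    uri=f"http://example.org/rel/{this.split()[1]}",
                    inverse_label=other,
                    inverse_uri=f"http://example.org/rel/{other.split()[1]}",
                    parent_label=parent,
                )
            )
            labels.append(this)
        i += 2 if inv != label else 1
    return terms
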