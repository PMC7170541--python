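"""Independent brute-force re-implementations used as test oracles.

These deliberately avoid the package's windowing/filtering code paths:
intervals are enumerated day by day, rules are re-derived from first
principles, and cue attribution is resolved by exhaustive pair enumeration.
"""

import datetime as dt
import re


def oracle_active(episodes, census):
    """Day-by-day scan of every episode interval."""
    out = set()
    for rec in episodes.itertuples(index=False):
        day = rec.start_date
        end = rec.end_date if rec.end_date is not None else census
        while day <= end and day <= census:
            if day == census:
                out.add(rec.patient_id)
            day += dt.timedelta(days=1)
    return out


def _block_of(code):
    m = re.match(r"^F(\d\d)", str(code).upper())
    if not m:
        return None
    n = int(m.group(1))
    return "F00-F03" if n <= 3 else ("F20-F29" if 20 <= n <= 29 else "other-F")


def oracle_dementia_index(stream, pid, census):
    dates = sorted(ev.date for ev in stream.diagnoses_for(pid)
                   if ev.icd10_category == "F00-F03" and ev.date <= census)
    return dates[0] if dates else None


def oracle_window_refs(stream, pid, census, window_days):
    window = {census - dt.timedelta(days=k) for k in range(window_days + 1)}
    return [r for r in stream.medications_for(pid) if r.date in window]


def oracle_recent_use(stream, pid, census, window_days, version,
                      min_refs=2):
    refs = oracle_window_refs(stream, pid, census, window_days)
    if version == "v1":
        return len(refs) > 0
    if len(refs) < min_refs:
        return False
    for ref in refs:
        drug_refs = [r for r in refs if r.drug_name == ref.drug_name]
        if not any(r.kind == "stop" for r in drug_refs):
            return True
    return False


def oracle_cohort_included(stream, episodes, census, window_days=183,
                           version="v2", sensitivity=False, min_refs=2):
    """Full re-derivation of cohort membership for one census."""
    included = set()
    for pid in set(episodes["patient_id"]):
        if pid not in oracle_active(episodes, census):
            continue
        index = oracle_dementia_index(stream, pid, census)
        if index is None:
            continue
        if not oracle_recent_use(stream, pid, census, window_days, version,
                                 min_refs):
            continue
        if sensitivity:
            events = [ev for ev in stream.diagnoses_for(pid) if ev.date <= census]
            if any(ev.icd10_category == "F20-F29" for ev in events):
                continue
            if any(ev.icd10_category != "F00-F03" and ev.date > index
                   for ev in events):
                continue
        included.add(pid)
    return included


def oracle_form_completed(forms, pid, census, validity_days):
    window = {census - dt.timedelta(days=k) for k in range(validity_days + 1)}
    for rec in forms.itertuples(index=False):
        if rec.patient_id == pid and rec.date in window:
            return True
    return False


def oracle_reverse_counts(stream, episodes, forms, census, window_days=183,
                          version="v2", validity_days=None):
    validity = validity_days if validity_days is not None else window_days
    denom = set()
    for pid in oracle_active(episodes, census):
        if oracle_dementia_index(stream, pid, census) is None:
            continue
        if not oracle_recent_use(stream, pid, census, window_days, version):
            denom.add(pid)
    numer = {pid for pid in denom
             if oracle_form_completed(forms, pid, census, validity)}
    return len(denom), len(numer)


# -- exhaustive cue-attribution oracle --------------------------------------

_WORD = re.compile(r"[A-Za-z0-9']+")


def oracle_attribute(sentence, targets, cues, span=5):
    """Resolve each target's cue by enumerating every (target, cue) pair.

    targets: surface word -> payload; cues: phrase -> kind with kind in
    {stop, start, negation}.  Returns payload -> resolved kind (or None).
    Ties on distance rank stop/negation above start.
    """
    tokens = [t.lower() for t in _WORD.findall(sentence)]
    strength = {"stop": 0, "negation": 0, "start": 1}
    results = {}
    for i, tok in enumerate(tokens):
        if tok not in targets:
            continue
        pairs = []
        for phrase, kind in cues.items():
            ph = [t.lower() for t in _WORD.findall(phrase)]
            for j in range(len(tokens) - len(ph) + 1):
                if tokens[j:j + len(ph)] != ph:
                    continue
                last = j + len(ph) - 1
                if last < i:
                    distance = i - last
                elif j > i:
                    distance = j - i
                else:
                    distance = 0
                if distance <= span:
                    pairs.append((distance, strength[kind], kind))
        results[targets[tok]] = min(pairs)[2] if pairs else None
    return results
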