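"""Independent reference implementations used only by the tests.

These deliberately avoid the code paths they check: the triple scan walks
the raw graph instead of going through SPARQL, and the placeholder
tokenizer is a character-level state machine independent of the
library's region-masking scanner.
"""

from collections import Counter


def scan_triples(graph, s=None, p=None, o=None):
    """Brute-force position-filtered scan of a graph.

    Returns the multiset of tuples of the *unfixed* positions (in S,P,O
    order) over all matching triples; with all three positions fixed,
    returns the number of matching triples.
    """
    rows = []
    count = 0
    for ts, tp, to in graph:
        if s is not None and ts != s:
            continue
        if p is not None and tp != p:
            continue
        if o is not None and to != o:
            continue
        count += 1
        proj = tuple(t for t, fixed in ((ts, s), (tp, p), (to, o)) if fixed is None)
        rows.append(proj)
    if s is not None and p is not None and o is not None:
        return count
    return Counter(rows)


def max_placeholder(text):
    """Largest N of any $N outside string literals, IRIREFs and comments."""
    i, n, best = 0, len(text), 0
    while i < n:
        c = text[i]
        if c in "\"'":
            if text[i:i + 3] == c * 3:
                end = text.find(c * 3, i + 3)
                i = n if end < 0 else end + 3
            else:
                j = i + 1
                while j < n and text[j] != c:
                    j += 2 if text[j] == "\\" else 1
                i = min(j + 1, n)
        elif c == "<":
            j = text.find(">", i + 1)
            if j >= 0 and all(ch not in " \t\n<" for ch in text[i + 1:j]):
                i = j + 1
            else:
                i += 1
        elif c == "#":
            j = text.find("\n", i)
            i = n if j < 0 else j
        elif c == "$":
            j = i + 1
            while j < n and text[j].isdigit():
                j += 1
            if j > i + 1:
                best = max(best, int(text[i + 1:j]))
            i = j
        else:
            i += 1
    return best


def nested_loop_join(graph_a, query_a, graph_b, query_b, join_variable, column=0):
    """Reference pipe semantics using rdflib directly: run the first query,
    then the second once per distinct value of the chosen output column
    with ``join_variable`` pre-bound; union all rows."""
    from rdflib import Variable

    first = list(graph_a.query(query_a))
    seen, distinct = set(), []
    for row in first:
        v = row[column]
        if v is not None and v not in seen:
            seen.add(v)
            distinct.append(v)
    rows = []
    for v in distinct:
        for row in graph_b.query(query_b, initBindings={Variable(join_variable): v}):
            rows.append(tuple(row))
    return Counter(rows)
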