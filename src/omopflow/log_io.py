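"""Event-log serialization: flat CSV and IEEE XES (via lxml).

CSV: one row per event with columns case_id, event_id, activity, timestamp,
originator, source_table, concept_id, event_row_id, then ``attr:<k>`` event
attributes and ``case:<k>`` case attributes (repeated per row).

XES: standard trace/event elements with concept:name for activity,
time:timestamp and org:resource; extra attributes keep their native type
(boolean/int/float/string).  ``read(write(log)) == log`` up to attribute
ordering.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd
from lxml import etree

from .extraction import Event, EventLog, Trace

_TS_FMT = "%Y-%m-%d %H:%M:%S"


def _encode(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, pd.Timestamp):
        return value.strftime(_TS_FMT)
    return str(value)


def _decode(text: str):
    if text == "":
        return None
    if text in ("true", "false"):
        return text == "true"
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def write_log_csv(log: EventLog, target: str | Path) -> Path:
    target = Path(target)
    attr_keys = sorted({k for t in log.traces for e in t.events
                        for k in e.attributes})
    case_keys = sorted({k for t in log.traces for k in t.attributes})
    header = (["case_id", "event_id", "activity", "timestamp", "originator",
               "source_table", "concept_id", "event_row_id"]
              + [f"attr:{k}" for k in attr_keys]
              + [f"case:{k}" for k in case_keys])
    with open(target, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for trace in log.traces:
            case_cells = [_encode(trace.attributes.get(k)) for k in case_keys]
            if not trace.events:
                writer.writerow([trace.case_id, "", "", "", "", "", "", ""]
                                + [""] * len(attr_keys) + case_cells)
            for e in trace.events:
                writer.writerow(
                    [trace.case_id, e.event_id, e.activity,
                     _encode(e.timestamp), e.originator, e.source_table,
                     _encode(e.concept_id), _encode(e.event_row_id)]
                    + [_encode(e.attributes.get(k)) for k in attr_keys]
                    + case_cells)
    return target


def read_log_csv(source: str | Path) -> EventLog:
    log = EventLog()
    traces: dict[str, Trace] = {}
    with open(source, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            case_id = row["case_id"]
            trace = traces.get(case_id)
            if trace is None:
                trace = Trace(case_id=case_id)
                for key, raw in row.items():
                    if key.startswith("case:"):
                        value = _decode(raw)
                        if value is not None:
                            trace.attributes[key[5:]] = value
                traces[case_id] = trace
                log.traces.append(trace)
            if row["event_id"] == "" and row["activity"] == "":
                continue  # placeholder row of an empty case
            attrs = {}
            for key, raw in row.items():
                if key.startswith("attr:"):
                    value = _decode(raw)
                    if value is not None:
                        attrs[key[5:]] = value
            trace.events.append(Event(
                event_id=row["event_id"], activity=row["activity"],
                timestamp=pd.Timestamp(row["timestamp"]),
                originator=row["originator"],
                source_table=row["source_table"],
                concept_id=_decode(row["concept_id"]),
                event_row_id=_decode(row["event_row_id"]),
                attributes=attrs))
    return log


_XES_NS = "http://www.xes-standard.org/"


def _xes_attr(parent, key: str, value) -> None:
    if value is None:
        return
    if isinstance(value, bool):
        etree.SubElement(parent, "boolean", key=key,
                         value="true" if value else "false")
    elif isinstance(value, int):
        etree.SubElement(parent, "int", key=key, value=str(value))
    elif isinstance(value, float):
        etree.SubElement(parent, "float", key=key, value=repr(value))
    elif isinstance(value, pd.Timestamp):
        etree.SubElement(parent, "date", key=key, value=value.isoformat())
    else:
        etree.SubElement(parent, "string", key=key, value=str(value))


def write_log_xes(log: EventLog, target: str | Path) -> Path:
    target = Path(target)
    root = etree.Element("log", attrib={"xes.version": "2.0",
                                        "xes.features": "nested-attributes"})
    for trace in log.traces:
        tr = etree.SubElement(root, "trace")
        _xes_attr(tr, "concept:name", trace.case_id)
        for k in sorted(trace.attributes):
            _xes_attr(tr, k, trace.attributes[k])
        for e in trace.events:
            ev = etree.SubElement(tr, "event")
            _xes_attr(ev, "concept:name", e.activity)
            _xes_attr(ev, "time:timestamp", e.timestamp)
            if e.originator:
                _xes_attr(ev, "org:resource", e.originator)
            _xes_attr(ev, "identity:id", e.event_id)
            if e.source_table:
                _xes_attr(ev, "source:table", e.source_table)
            if e.concept_id is not None:
                _xes_attr(ev, "source:concept_id", int(e.concept_id))
            if e.event_row_id is not None:
                _xes_attr(ev, "source:row_id", int(e.event_row_id))
            for k in sorted(e.attributes):
                _xes_attr(ev, k, e.attributes[k])
    tree = etree.ElementTree(root)
    tree.write(str(target), pretty_print=True, xml_declaration=True,
               encoding="UTF-8")
    return target


def _xes_value(el):
    tag = etree.QName(el).localname
    raw = el.get("value")
    if tag == "boolean":
        return raw == "true"
    if tag == "int":
        return int(raw)
    if tag == "float":
        return float(raw)
    if tag == "date":
        return pd.Timestamp(raw)
    return raw


def read_log_xes(source: str | Path) -> EventLog:
    tree = etree.parse(str(source))
    root = tree.getroot()
    log = EventLog()
    for tr in root.iter("{*}trace" if root.nsmap.get(None) else "trace"):
        trace = Trace(case_id="")
        for child in tr:
            tag = etree.QName(child).localname
            if tag == "event":
                e = Event(event_id="", activity="",
                          timestamp=pd.Timestamp("1970-01-01"))
                for a in child:
                    key = a.get("key")
                    value = _xes_value(a)
                    if key == "concept:name":
                        e.activity = value
                    elif key == "time:timestamp":
                        e.timestamp = value
                    elif key == "org:resource":
                        e.originator = value
                    elif key == "identity:id":
                        e.event_id = value
                    elif key == "source:table":
                        e.source_table = value
                    elif key == "source:concept_id":
                        e.concept_id = value
                    elif key == "source:row_id":
                        e.event_row_id = value
                    else:
                        e.attributes[key] = value
                trace.events.append(e)
            else:
                key = child.get("key")
                value = _xes_value(child)
                if key == "concept:name":
                    trace.case_id = str(value)
                else:
                    trace.attributes[key] = value
        log.traces.append(trace)
    return log


def write_log(log: EventLog, target: str | Path, format: str = "csv") -> Path:
    if format == "csv":
        return write_log_csv(log, target)
    if format == "xes":
        return write_log_xes(log, target)
    raise ValueError(f"unknown log format {format!r}")


def read_log(source: str | Path, format: str = "csv") -> EventLog:
    if format == "csv":
        return read_log_csv(source)
    if format == "xes":
        return read_log_xes(source)
    raise ValueError(f"unknown log format {format!r}")


def logs_equal(a: EventLog, b: EventLog) -> bool:
    """Field-by-field equality up to attribute ordering (round-trip oracle).

    Timestamps compare at second resolution; attribute values compare after
    text round-tripping so 1.0 == 1 distinctions in containers don't matter.
    """
    if len(a.traces) != len(b.traces):
        return False
    for ta, tb in zip(a.traces, b.traces):
        if ta.case_id != tb.case_id:
            return False
        if {k: _encode(v) for k, v in ta.attributes.items() if v is not None} \
                != {k: _encode(v) for k, v in tb.attributes.items()
                    if v is not None}:
            return False
        if len(ta.events) != len(tb.events):
            return False
        for ea, eb in zip(ta.events, tb.events):
            if (ea.event_id != eb.event_id or ea.activity != eb.activity
                    or _encode(ea.timestamp) != _encode(eb.timestamp)
                    or (ea.originator or "") != (eb.originator or "")
                    or (ea.source_table or "") != (eb.source_table or "")
                    or (ea.concept_id or None) != (eb.concept_id or None)
                    or (ea.event_row_id or None) != (eb.event_row_id or None)):
                return False
            aa = {k: _encode(v) for k, v in ea.attributes.items()
                  if v is not None}
            ab = {k: _encode(v) for k, v in eb.attributes.items()
                  if v is not None}
            if aa != ab:
                return False
    return True
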