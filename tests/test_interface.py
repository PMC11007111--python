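"""Graph export, prompt assembly/validation, and the command-line surface."""

import networkx as nx
import pytest
from click.testing import CliRunner

import textode as tx
from textode.cli import main
from textode.graphs import export_graph, model_to_graph
from textode.prompts import PromptTemplate, build_llm_prompt, validate_llm_output

BIND = "A binds B --> AB\n@init A = 1\n@init B = 1\n"


class TestGraphExport:
    def test_bind_model_bipartite_structure(self):
        m = tx.compile_model(tx.parse_model(BIND))
        g = model_to_graph(m)
        species = [n for n, d in g.nodes(data=True) if d["kind"] == "species"]
        reactions = [n for n, d in g.nodes(data=True) if d["kind"] == "reaction"]
        assert sorted(species) == ["A", "AB", "B"]
        assert reactions == ["r1"]
        assert g.has_edge("A", "r1") and g.has_edge("B", "r1") and g.has_edge("r1", "AB")

    def test_catalytic_edges_styled_distinctly(self):
        m = tx.compile_model(tx.parse_model("E phosphorylates S --> pS\n"))
        dot = export_graph(m, "dot")
        assert "style=dashed" in dot

    def test_diamond_graph_contains_the_loop(self):
        m = tx.compile_model(tx.parse_model(tx.fixtures.make_diamond_model()))
        g = model_to_graph(m).to_undirected()
        cycles = nx.cycle_basis(g)
        assert any(len(c) >= 8 for c in cycles)  # 4 species + 4 reaction nodes

    def test_graphml_output_parses(self):
        m = tx.compile_model(tx.parse_model(BIND))
        text = export_graph(m, "graphml")
        back = nx.parse_graphml(text)
        assert set(back.nodes) == {"A", "B", "AB", "r1"}

    def test_weighted_network_attributes_exported(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        res = tx.EnrichmentResult("q", 0.5, {"A": 2.5}, {frozenset({"A", "B"}): 1.5}, 10, 4)
        from textode.litweights import annotate_network

        dot = export_graph(annotate_network(g, res), "dot")
        assert "width=2.5" in dot and "penwidth=1.5" in dot

    def test_unknown_format_rejected(self):
        m = tx.compile_model(tx.parse_model(BIND))
        with pytest.raises(ValueError, match="unknown graph format"):
            export_graph(m, "svg")


VALID_TEMPLATE = PromptTemplate(
    task_description="Transcribe the pathway description.",
    exemplar_passage="Kinase K phosphorylates substrate S.",
    exemplar_model_text="K phosphorylates S --> pS\npS is dephosphorylated --> S\n",
    target_passage="Receptor R binds ligand L, and the complex is degraded.",
)


class TestPrompt:
    def test_three_parts_in_order_with_exemplar_verbatim(self):
        prompt = build_llm_prompt(VALID_TEMPLATE)
        i_task = prompt.index("## Task")
        i_ex = prompt.index("## Example passage")
        i_target = prompt.index("## Passage")
        assert i_task < i_ex < i_target
        assert "K phosphorylates S --> pS" in prompt

    def test_deterministic(self):
        assert build_llm_prompt(VALID_TEMPLATE) == build_llm_prompt(VALID_TEMPLATE)

    def test_empty_target_rejected(self):
        bad = PromptTemplate(
            VALID_TEMPLATE.task_description, VALID_TEMPLATE.exemplar_passage,
            VALID_TEMPLATE.exemplar_model_text, "   ",
        )
        with pytest.raises(ValueError, match="target_passage"):
            build_llm_prompt(bad)

    def test_broken_exemplar_rejected(self):
        bad = PromptTemplate(
            VALID_TEMPLATE.task_description, VALID_TEMPLATE.exemplar_passage,
            "K magically activates S\n", VALID_TEMPLATE.target_passage,
        )
        with pytest.raises(ValueError, match="does not parse"):
            build_llm_prompt(bad)


class TestValidateLlmOutput:
    def test_clean_model_no_issues(self):
        model, issues = validate_llm_output(
            "A is phosphorylated --> pA\npA is degraded\n@init A = 1\n"
        )
        assert model is not None
        assert issues == []

    def test_dead_end_product_flagged(self):
        model, issues = validate_llm_output("E phosphorylates S --> pS\n@init S = 1\n@init E = 1\n")
        assert any("never reverts" in i.message for i in issues)

    def test_unconstrained_loop_flagged(self):
        model, issues = validate_llm_output(tx.fixtures.make_diamond_model())
        assert any("detailed-balance" in i.message for i in issues)

    def test_unparseable_line_reported_remainder_parsed(self):
        model, issues = validate_llm_output(
            "A is degraded\nB mumbles C\n@init A = 1\n"
        )
        assert model is not None and len(model.reactions) == 1
        assert any(i.severity == "error" and i.line_number == 2 for i in issues)


@pytest.fixture
def runner():
    return CliRunner()


@pytest.fixture
def model_file(tmp_path):
    p = tmp_path / "decay.txt"
    p.write_text("A is degraded | kf=0.5\n@init A = 1\n@obs A: A\n")
    return p


class TestCli:
    def test_compile_report(self, runner, model_file):
        r = runner.invoke(main, ["compile", str(model_file)])
        assert r.exit_code == 0
        assert "kf_r1" in r.output

    def test_compile_graph_output(self, runner, model_file, tmp_path):
        out = tmp_path / "g.dot"
        r = runner.invoke(main, ["compile", str(model_file), "--graph", "dot", "--out", str(out)])
        assert r.exit_code == 0
        assert out.read_text().startswith("digraph")

    def test_simulate_writes_tidy_table(self, runner, model_file):
        r = runner.invoke(main, ["simulate", str(model_file), "--duration", "2", "--n-times", "5"])
        assert r.exit_code == 0
        header = r.output.splitlines()[0].split("\t")
        assert header == ["condition", "observable", "time", "value", "normalized_value"]

    def test_parse_error_exits_nonzero_naming_line(self, runner, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("A frobnicates B\n")
        r = runner.invoke(main, ["compile", str(p)])
        assert r.exit_code != 0
        assert "line 1" in r.output

    def test_kgml2text_and_fixture_generators(self, runner, tmp_path):
        xml = tmp_path / "toy.xml"
        r = runner.invoke(main, ["fixtures", "toy-kgml", "--n-genes", "3",
                                 "--n-relations", "2", "--seed", "1", "--out", str(xml)])
        assert r.exit_code == 0
        out = tmp_path / "model.txt"
        r = runner.invoke(main, ["kgml2text", str(xml), "--out", str(out)])
        assert r.exit_code == 0
        tx.parse_model(out.read_text())

    def test_weigh_outputs_graphml(self, runner, tmp_path):
        corpus = tmp_path / "corpus.tsv"
        r = runner.invoke(main, ["fixtures", "toy-corpus", "--genes", "A,B",
                                 "--query", "MCF-7", "--enriched", "A",
                                 "--n-docs", "50", "--seed", "2", "--out", str(corpus)])
        assert r.exit_code == 0
        out = tmp_path / "w.graphml"
        r = runner.invoke(main, ["weigh", str(corpus), "--genes", "A,B",
                                 "--edges", "A-B", "--query", "MCF-7", "--out", str(out)])
        assert r.exit_code == 0
        g = nx.parse_graphml(out.read_text())
        assert set(g.nodes) == {"A", "B"}

    def test_prompt_subcommand(self, runner, tmp_path):
        files = {}
        for name, content in [
            ("task", "Transcribe reactions.\n"),
            ("expass", "K phosphorylates S.\n"),
            ("exmodel", "K phosphorylates S --> pS\n"),
            ("target", "R binds L.\n"),
        ]:
            p = tmp_path / name
            p.write_text(content)
            files[name] = str(p)
        r = runner.invoke(main, ["prompt", "--task", files["task"],
                                 "--exemplar-passage", files["expass"],
                                 "--exemplar-model", files["exmodel"],
                                 "--target", files["target"]])
        assert r.exit_code == 0
        assert "## Passage" in r.output

    def test_sensitivity_subcommand(self, runner, model_file):
        r = runner.invoke(main, ["sensitivity", str(model_file), "--observable", "A",
                                 "--reducer", "value_at_time", "--time", "2.0"])
        assert r.exit_code == 0
        assert "kf_r1" in r.output
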