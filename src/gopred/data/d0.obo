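format-version: 1.2
ontology: gopred-d0

[Term]
id: GO:0000001
name: biological_process
namespace: biological_process

[Term]
id: GO:0000002
name: term A
namespace: biological_process
is_a: GO:0000001 ! biological_process

[Term]
id: GO:0000003
name: term B
namespace: biological_process
is_a: GO:0000001 ! biological_process

[Term]
id: GO:0000004
name: term A1
namespace: biological_process
is_a: GO:0000002 ! term A

[Term]
id: GO:0000005
name: term A2
namespace: biological_process
is_a: GO:0000002 ! term A
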