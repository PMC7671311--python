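format-version: 1.2
ontology: worked-example

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: process A
namespace: biological_process
is_a: GO:0000001 ! root process

[Term]
id: GO:0000003
name: process B
namespace: biological_process
is_a: GO:0000001 ! root process

[Term]
id: GO:0000004
name: process A1
namespace: biological_process
is_a: GO:0000002 ! process A

[Term]
id: GO:0000005
name: process A2
namespace: biological_process
is_a: GO:0000002 ! process A

[Term]
id: GO:0000006
name: process B1
namespace: biological_process
is_a: GO:0000003 ! process B
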