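id	group	age	sex	batch	variant	gene
SETD2-R1740Q-P1	SETD2-R1740Q	12	F	B1	c.5219G>A	SETD2
SETD2-R1740Q-P2	SETD2-R1740Q	5	M	B1	c.5219G>A	SETD2
SETD2-R1740W-P1	SETD2-R1740W	0.5	M	B1	c.5218C>T	SETD2
SETD2-R1740W-P2	SETD2-R1740W	10	M	B1	c.5218C>T	SETD2
SETD2-R1740W-P3	SETD2-R1740W	10	F	B1	c.5218C>T	SETD2
SETD2-R1740W-P4	SETD2-R1740W	12	F	B1	c.5218C>T	SETD2
SETD2-LLS-P1	SETD2-LLS	12	M	B1	c.4438_4441del	SETD2
SETD2-LLS-P2	SETD2-LLS	4.5	M	B1	c.1647_1667delinsTG	SETD2
SETD2-LLS-P3	SETD2-LLS	2	M	B1	c.513del	SETD2
SETD2-LLS-P4	SETD2-LLS	20	F	B1	c.4457_4460delAGAA	SETD2
SETD1A-P1	SETD1A	3	M	B1	c.4582-2_4582-1del	SETD1A
SETD1A-P2	SETD1A	17	F	B1	c.4582-2_4582-1del	SETD1A
SETD1A-P3	SETD1A	13	F	B1	c.4582-2_4582-1del	SETD1A
SETD1A-P4	SETD1A	3	F	B1	c.4711C>T	SETD1A
SETD1A-P5	SETD1A	7	F	B1	c.2289dup	SETD1A
SETD1A-P6	SETD1A	12	F	B1	852kb_del	SETD1A
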