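# Reference word -> stem pairs for the original (1980) Porter algorithm.
# Rows tagged with a step name are the rule examples published in the
# algorithm's description and apply to that single step in isolation;
# rows tagged "all" are published whole-algorithm examples.
# Columns: step <TAB> input <TAB> expected
1a	caresses	caress
1a	ponies	poni
1a	ties	ti
1a	caress	caress
1a	cats	cat
1b	feed	feed
1b	agreed	agree
1b	plastered	plaster
1b	bled	bled
1b	motoring	motor
1b	sing	sing
1b	conflated	conflate
1b	troubled	trouble
1b	sized	size
1b	hopping	hop
1b	tanned	tan
1b	falling	fall
1b	hissing	hiss
1b	fizzed	fizz
1b	failing	fail
1b	filing	file
1c	happy	happi
1c	sky	sky
2	relational	relate
2	conditional	condition
2	rational	rational
2	valenci	valence
2	hesitanci	hesitance
2	digitizer	digitize
2	conformabli	conformable
2	radicalli	radical
2	differentli	different
2	vileli	vile
2	analogousli	analogous
2	vietnamization	vietnamize
2	predication	predicate
2	operator	operate
2	feudalism	feudal
2	decisiveness	decisive
2	hopefulness	hopeful
2	callousness	callous
2	formaliti	formal
2	sensitiviti	sensitive
2	sensibiliti	sensible
3	triplicate	triplic
3	formative	form
3	formalize	formal
3	electriciti	electric
3	electrical	electric
3	hopeful	hope
3	goodness	good
4	revival	reviv
4	allowance	allow
4	inference	infer
4	airliner	airlin
4	gyroscopic	gyroscop
4	adjustable	adjust
4	defensible	defens
4	irritant	irrit
4	replacement	replac
4	adjustment	adjust
4	dependent	depend
4	adoption	adopt
4	homologou	homolog
4	communism	commun
4	activate	activ
4	angulariti	angular
4	homologous	homolog
4	effective	effect
4	bowdlerize	bowdler
5	probate	probat
5	rate	rate
5	cease	ceas
5	controll	control
5	roll	roll
all	connect	connect
all	connected	connect
all	connecting	connect
all	connection	connect
all	connections	connect
all	relate	relat
all	generalizations	gener
all	oscillators	oscil
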