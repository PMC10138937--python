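# Default conversion-rule table: PATTERN <TAB> KIND <TAB> SLOT_MAP
# Earlier rows win ties (higher priority). Patterns are matched
# case-insensitively against whole clauses; species slots tolerate role
# words ("the", "protein", "complex", ...) before the actual name.
[the] [initial] concentration [of {x:SPECIES}] is {q:QUANTITY}	INITIAL_CONCENTRATION	x=substrate,q=quantity
{x:SPECIES} concentration is {q:QUANTITY}	INITIAL_CONCENTRATION	x=substrate,q=quantity
{x:SPECIES_LIST} (is|are) (degraded|decayed) by {e:SPECIES}	DEGRADATION	x=substrates,e=catalyst
{x:SPECIES_LIST} (degrades|degrade|decays|decay)	DEGRADATION	x=substrates
{x:SPECIES} (is|are) [then] converted (into|to) {y:SPECIES_LIST} through [the] (intermediates|intermediate) {i:SPECIES_LIST}	CONVERSION	x=substrate,y=products,i=intermediates
{x:SPECIES} (is|are) [then] converted (into|to) {y:SPECIES_LIST}	CONVERSION	x=substrate,y=products
two {x:SPECIES} (bind|binds) [reversibly] [to] form {z:SPECIES}	BINDING	x=substrate,z=product,stoich:2,reversible:true
{x:SPECIES} and {y:SPECIES} [can] (bind|binds) [reversibly] [to] form {z:SPECIES}	BINDING	x=substrate,y=substrate2,z=product,reversible:true
{x:SPECIES} [can] (bind|binds) [reversibly] to {y:SPECIES} (and|to) (form|forms) {z:SPECIES}	BINDING	x=substrate,y=substrate2,z=product,reversible:true
{x:SPECIES} dissociates (into|to) {y:SPECIES} and {z:SPECIES}	DISSOCIATION	x=substrate,y=product,z=product2
[the] [metabolic] (reactions|reaction) (are|is) catalyzed by {e:SPECIES_LIST}	CATALYSIS	e=catalysts
{x:SPECIES_LIST} (is|are) expressed	EXPRESSION	x=targets
{x:SPECIES_LIST} (is|are) (synthesized|produced) from {t:SPECIES}	SYNTHESIS	x=targets,t=template
{x:SPECIES_LIST} (is|are) (synthesized|produced)	SYNTHESIS	x=targets
{r:SPECIES} activates [the] (expression|synthesis) of {y:SPECIES_LIST}	REGULATION	r=regulator,y=targets,sign:activation
{r:SPECIES} represses [the] (expression|synthesis) of {y:SPECIES_LIST}	REGULATION	r=regulator,y=targets,sign:repression
{x:SPECIES} is {q:QUANTITY}	INITIAL_CONCENTRATION	x=substrate,q=quantity
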